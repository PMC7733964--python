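"""Preprocessing contracts: viability filter, gating, scaling, subsampling."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

import emtsig as es
from emtsig.data import Snapshot, SnapshotDataset


def make_snapshot(df: pd.DataFrame, **meta) -> Snapshot:
    meta.setdefault("time", 0.0)
    meta.setdefault("replicate", 1)
    return Snapshot(data=df, **meta)


class TestFilterDead:
    def test_strict_inequality_at_the_count_cutoff(self):
        s = make_snapshot(pd.DataFrame({"cPARP": [0.0, 20.0, 21.0], "x": [1.0, 2.0, 3.0]}))
        out = es.filter_dead(s, threshold=20)
        assert out.data["cPARP"].tolist() == [0.0, 20.0]
        assert out.data["x"].tolist() == [1.0, 2.0]

    def test_all_dead_yields_empty_snapshot_with_warning(self):
        s = make_snapshot(pd.DataFrame({"cPARP": [30.0, 40.0]}))
        with pytest.warns(UserWarning, match="empty"):
            out = es.filter_dead(s, threshold=20)
        assert out.n_cells == 0

    def test_infinite_threshold_is_identity(self):
        s = make_snapshot(pd.DataFrame({"cPARP": [0.0, 500.0], "x": [1.0, 2.0]}))
        out = es.filter_dead(s, threshold=math.inf)
        assert out.data.equals(s.data)

    def test_missing_channel_raises_naming_it(self):
        s = make_snapshot(pd.DataFrame({"x": [1.0]}))
        with pytest.raises(KeyError, match="cPARP"):
            es.filter_dead(s)


class TestGating:
    def epithelial_gate(self):
        return es.GateSpec(marker_high=("Ecad", 110.0), marker_low=("Vim", 110.0),
                           label="epithelial")

    def test_separated_epithelial_population_is_mostly_retained(self):
        cfg = es.PhenotypeConfig.from_config(label="epithelial", n_cells_per_snapshot=2000)
        _, markers = es.generate_cell_population(cfg, seed=8)
        s = make_snapshot(markers)
        out = es.gate_phenotype(s, self.epithelial_gate())
        assert out.n_cells >= 0.95 * s.n_cells
        assert out.phenotype == "epithelial"

    def test_mesenchymal_population_leaks_little_into_epithelial_gate(self):
        cfg = es.PhenotypeConfig.from_config(label="mesenchymal", n_cells_per_snapshot=2000)
        _, markers = es.generate_cell_population(cfg, seed=8)
        out = es.gate_phenotype(make_snapshot(markers), self.epithelial_gate())
        assert out.n_cells <= 0.05 * 2000

    def test_extreme_thresholds_retain_everything(self):
        df = pd.DataFrame({"Ecad": [1.0, 2.0], "Vim": [1.0, 2.0]})
        gate = es.GateSpec(marker_high=("Ecad", 1e-12), marker_low=("Vim", math.inf))
        out = es.gate_phenotype(make_snapshot(df), gate)
        assert out.n_cells == 2

    def test_gate_and_filter_commute(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {
                "Ecad": rng.lognormal(5, 1, 200),
                "Vim": rng.lognormal(4, 1, 200),
                "cPARP": rng.poisson(15, 200).astype(float),
            }
        )
        s = make_snapshot(df)
        gate = self.epithelial_gate()
        a = es.gate_phenotype(es.filter_dead(s), gate)
        b = es.filter_dead(es.gate_phenotype(s, gate))
        assert a.data.reset_index(drop=True).equals(b.data.reset_index(drop=True))


class TestScaling:
    def _dataset(self, phospho, total):
        df = pd.DataFrame({"pMEK": phospho, "MEK": total})
        panel = {"phospho": ["pMEK"], "totals": {"pMEK": "MEK"},
                 "phenotype_markers": [], "viability": "cPARP"}
        return SnapshotDataset([make_snapshot(df, phenotype="epithelial")]), panel

    def test_compliant_data_is_untouched(self):
        d, panel = self._dataset([1.0, 2.0, 3.0], [10.0, 10.0, 10.0])
        out, report = es.scale_phospho_to_total(d, panel)
        assert report["factor"].tolist() == [1.0]
        assert out[0].data.equals(d[0].data)

    def test_doubled_phospho_gets_half_factor(self):
        total = np.linspace(10, 20, 50)
        d, panel = self._dataset(2.0 * total, total)
        _, report = es.scale_phospho_to_total(d, panel, quantile=0.999)
        assert report["factor"].item() == pytest.approx(0.5, rel=1e-6)

    def test_postcondition_ratio_below_one_everywhere(self):
        rng = np.random.default_rng(0)
        total = rng.lognormal(3, 0.3, 500)
        phospho = total * rng.lognormal(0, 0.6, 500)
        d, panel = self._dataset(phospho, total)
        out, _ = es.scale_phospho_to_total(d, panel)
        ratio = out[0].data["pMEK"] / out[0].data["MEK"]
        assert np.all(ratio <= 1.0)

    def test_idempotent_within_tolerance(self):
        rng = np.random.default_rng(1)
        total = rng.lognormal(3, 0.3, 400)
        d, panel = self._dataset(total * rng.lognormal(0.2, 0.4, 400), total)
        once, _ = es.scale_phospho_to_total(d, panel)
        _, report2 = es.scale_phospho_to_total(once, panel)
        assert abs(report2["factor"].item() - 1.0) < 1e-12

    def test_zero_total_channel_rejected(self):
        d, panel = self._dataset([1.0, 1.0], [0.0, 0.0])
        with pytest.raises(ValueError, match="entirely zero"):
            es.scale_phospho_to_total(d, panel)


class TestSubsampling:
    def _replicates(self, sizes):
        snaps = []
        for rep, size in enumerate(sizes, start=1):
            df = pd.DataFrame({"x": np.arange(size, dtype=float)})
            snaps.append(make_snapshot(df, replicate=rep))
        return SnapshotDataset(snaps)

    def test_proportional_allocation(self):
        d = self._replicates([1000, 2000, 3000])
        out = es.subsample_across_replicates(d, n=600, seed=4)
        assert [s.n_cells for s in out] == [100, 200, 300]

    def test_requesting_everything_is_identity_up_to_order(self):
        d = self._replicates([40, 60])
        out = es.subsample_across_replicates(d, n=100, seed=4)
        assert sum(s.n_cells for s in out) == 100

    def test_oversubscription_keeps_all_and_warns(self):
        d = self._replicates([10, 10])
        with pytest.warns(UserWarning, match="keeping all"):
            out = es.subsample_across_replicates(d, n=50, seed=4)
        assert sum(s.n_cells for s in out) == 20

    def test_seeded_reproducibility(self):
        d = self._replicates([300, 500])
        a = es.subsample_across_replicates(d, n=200, seed=11)
        b = es.subsample_across_replicates(d, n=200, seed=11)
        for s1, s2 in zip(a, b):
            assert s1.data.equals(s2.data)

    def test_draw_is_without_replacement(self):
        d = self._replicates([500])
        out = es.subsample_across_replicates(d, n=400, seed=2)
        vals = out[0].data["x"].to_numpy()
        assert len(np.unique(vals)) == len(vals)


class TestLogTransform:
    def test_closed_forms(self):
        s = make_snapshot(pd.DataFrame({"x": [0.0, math.e - 1.0]}))
        out = es.log_transform(s, "log1p")
        assert out.data["x"].tolist() == pytest.approx([0.0, 1.0])
        s2 = make_snapshot(pd.DataFrame({"x": [3.0]}))
        assert es.log_transform(s2, "log2").data["x"].item() == pytest.approx(2.0)

    def test_negative_input_rejected(self):
        df = pd.DataFrame({"x": [1.0]})
        snap = make_snapshot(df)
        snap.data.loc[0, "x"] = -1.0  # bypass construction check
        with pytest.raises(ValueError):
            es.log_transform(snap, "log1p")

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            es.log_transform(make_snapshot(pd.DataFrame({"x": [1.0]})), "sqrt")


def test_full_preprocess_keeps_channel_inventory(tiny_study):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prep, report = es.preprocess_dataset(tiny_study["epithelial"], "epithelial", seed=3)
    assert set(prep[0].channels) == set(tiny_study["epithelial"][0].channels)
    assert (report["factor"] <= 1.0).all()
    assert all(s.phenotype == "epithelial" for s in prep)
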