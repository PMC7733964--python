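# Default analysis configuration and schema for emtsig.
#
# Every tunable default of the package lives here: the measurement panel,
# the sampling design, the reference kinetic parameters, generator settings
# for both phenotypes, preprocessing thresholds, network-inference settings,
# the distribution-matching cost, optimizer budgets, the sensitivity grid and
# the reconciliation slack.  `emtsig.config.load_default_config()` returns this
# document as a dict; `validate_config()` checks any user-supplied variant
# against the schema implied by this file.

panel:
  phospho: [pMEK, ppERK, pRSK, pAKT, pGSK3b, pS6]
  totals:                      # phospho channel -> matching total-protein channel
    pMEK: MEK
    ppERK: ERK
    pRSK: RSK
    pAKT: AKT
    pGSK3b: GSK3b
    pS6: S6
  phenotype_markers: [Ecad, Vim]
  viability: cPARP             # cleaved PARP, counts

design:
  # minutes relative to EGF addition; t <= 0 samples are pre-stimulation
  time_grid: [-10, -5, 0, 1, 3, 5, 8, 12, 15, 20, 30, 50]
  control_times: [0, 5, 15, 50]   # unstimulated controls, 4 time points
  n_replicates: 3

parameters:
  epithelial:
    # aggregated inputs: magnitude I, onset delay tau [min], decay d [1/min]
    I1: 5.3
    tau1: 0.5
    d1: 0.08
    I2: 8.1
    tau2: 0.5
    d2: 0.05
    # pRAF block (unmeasured): activation kR, input order gR, PI3K crosstalk
    # order gc1, deactivation order hR, deactivation rate gammaR, capacity RT
    kR: 0.04
    gR: 1.0
    gc1: 0.5
    hR: 1.0
    gammaR: 1.0
    RT: 10.0
    # PI3K block (unmeasured, no explicit capacity)
    kP: 0.5
    gP: 1.0
    hP: 1.0
    gammaP: 0.5
    # measured cascade species: activation rate k, upstream order g,
    # deactivation order h (deactivation rates are cell-specific)
    k1: 0.10    # MEK <- pRAF
    g1: 1.0
    h1: 1.0
    k2: 0.05    # ERK <- pMEK
    g2: 1.0
    h2: 1.0
    k3: 0.04    # RSK <- ppERK
    g3: 1.0
    h3: 1.0
    k4: 0.03    # AKT <- PI3K*
    g4: 1.0
    h4: 1.0
    k5: 1.0e-3  # GSK3b <- pAKT
    g5: 1.0
    h5: 0.3     # near zero-order pGSK3b dephosphorylation
    k12: 1.0e-3 # GSK3b <- pRSK crosstalk
    g12: 1.0
    k6: 2.0e-5  # S6 <- pRSK
    g6: 1.0
    h6: 1.0
    k13: 1.585e-8  # S6 <- pAKT branch, 10^-7.8
    g13: 3.0
  # mesenchymal preset = epithelial with I1=1.9, I2=55, h5=0.05, k13=10^-9.5
  # (constructed programmatically by emtsig.params.ground_truth_presets)

generator:
  shared:
    n_cells_per_snapshot: 1000
    total_means: {MEK: 120.0, ERK: 160.0, RSK: 100.0, AKT: 140.0, GSK3b: 90.0, S6: 200.0}
    total_cv: 0.30
    total_correlation: 0.30
    baseline_phospho_fraction:
      pMEK: 0.15
      ppERK: 0.10
      pRSK: 0.12
      pAKT: 0.20
      pGSK3b: 0.25
      pS6: 0.15
    baseline_cv: 0.20
    marker_cv: 0.50
    dead_fraction: 0.05
    noise_cv: 0.15
  epithelial:
    ecad_vim_modes: [400.0, 30.0]   # [E-cadherin mode, vimentin mode]
  mesenchymal:
    ecad_vim_modes: [30.0, 400.0]

preprocessing:
  dead_threshold_counts: 20        # cells with cPARP > 20 counts are removed
  gates:
    epithelial: {marker_high: [Ecad, 110.0], marker_low: [Vim, 110.0]}
    mesenchymal: {marker_high: [Vim, 110.0], marker_low: [Ecad, 110.0]}
  scale_quantile: 0.999            # phospho/total ratio quantile forced <= 1
  subsample_n: 500                 # cells per time point across replicates

network:
  threshold: 0.1                   # |partial correlation| for an edge
  include_totals: false
  canonical_edges:
    - [pMEK, ppERK]
    - [ppERK, pRSK]
    - [pRSK, pS6]
    - [pAKT, pGSK3b]

cost:
  transform: log2                  # log2(x + offset) on cost channels
  offset: 1.0
  estimator: biased                # V-statistic MMD^2; 'unbiased' for reporting
  bandwidth_cap: 2000              # subsample cap for the median heuristic
  n_sim_cells: 100                 # ensemble size per cost evaluation

fit:
  budgets:
    desk:  {n_samples: 2000, n_keep: 10, round_iters: 100, max_rounds: 1,
            n_deep: 3, deep_max_rounds: 4,
            final_round_iters: 100, final_max_rounds: 3}
    paper: {n_samples: 50000, n_keep: 200, round_iters: 300, max_rounds: 25,
            n_deep: 0, deep_max_rounds: 0,
            final_round_iters: 300, final_max_rounds: 50}
  improve_frac: 0.02               # a round must improve cost by 2% to continue
  final_tol: 1.0e-4                # final refinement stops below this rel. change
  n_screen_cells: 40               # cheaper ensemble used to score global draws
  simplex_step: 0.15               # initial simplex edge (log10 decades)
  # log-uniform search ranges: half-widths in log2 units around the reference
  # values (kinetic orders get a narrower prior: values above ~4 are not
  # biochemically plausible); explicit ranges for special cases
  range_log2_halfwidth: 2.0
  range_log2_halfwidth_orders: 0.25
  range_overrides:
    I1: [1.0, 64.0]
    I2: [1.0, 64.0]
    tau1: [0.0, 3.0]               # delays: linear scale
    tau2: [0.0, 3.0]
    d1: [0.04, 0.16]               # EGF-pulse decay: timescale 6-25 min
    d2: [0.025, 0.1]

sensitivity:
  grid_lo: -8.0                    # log2 fold-change range ...
  grid_hi: 3.0
  grid_step: 0.25                  # ... in increments of 0.25 -> 45 offsets

reconciliation:
  slack: 0.01                      # allowed relative cost increase (1%)
  tol_log2: 0.1                    # |log2 difference| above which params differ
  n_candidates: 11                 # line-search points per greedy merge
  polish_iters: 150
  sparsity_weight: 0.0             # phase-0 transfer refit weight (0 = off; use
                                   # for best-fit pairs from unrelated basins)
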