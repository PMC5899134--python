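# Methods

## Competitive translation model

Translation of each mRNA species is coarse-grained into a ribosome-flow
chain: an RBS state `p` (probability the RBS is ribosome-bound but not yet
initiated) followed by `n` elongation sites `x₁…xₙ`, one per 30 bp of
coding sequence (the ~10-codon ribosome footprint). `n` is the nearest
integer to L/30 with ties rounded up and a floor of one site; 720 bp (the
monitor's sfGFP) gives exactly 24 sites.

A free ribosome binds an unoccupied RBS at rate `a₊·R_free`, then either
unbinds (`a₋`) or initiates onto the first site (`b₀`), subject to hard
exclusion (initiation requires site 1 to be empty, and a ribosome can only
hop into an empty site). Every elongation step of a given gene proceeds at
the same lumped rate γ, which absorbs all sequence-specific elongation
costs (codon usage, structure, amino-acid supply); the final γ step also
releases the ribosome back to the pool — there is no separate termination
rate. All per-construct rates derive from the monitor's reference values
through the dimensionless relative RBS strength:
`a₊ = a₊M·s`, `a₋ = a₋M/s`, `b₀ = b₀M·s`.

Species are coupled **only** through the free pool,
`R_free = R_total − Σₛ [mRNAₛ]·(pₛ + Σᵢ xₛᵢ)`, which is always computed from
conservation and never integrated as a state. RBS-bound but uninitiated
ribosomes therefore count against the pool. Mean-field factorisation is
assumed (occupancy correlations between adjacent sites are neglected), as
is standard for ribosome-flow models.

Steady-state protein output of species *s* is `γₛ·xₙ·[mRNAₛ]` (nM s⁻¹).
The assay statistic is the **normalized capacity**: monitor output with
competitors present divided by monitor output alone; it is 1.0 by
construction with no competitor and decreases with competitor mRNA level,
RBS strength, and 1/γ.

Operons are expanded to one species per cistron, each at the full
promoter-determined transcript concentration with its own RBS strength,
length and γ: on a polycistronic message every RBS is an independent
ribosome entry point, and the per-gene parameterisation carries no
inter-cistron coupling (no reinitiation or translational coupling).

### Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `a₊M` | 1e-4 | (rib·RBS)⁻¹ s⁻¹ | monitor ribosome binding rate |
| `a₋M` | 200 | s⁻¹ | monitor unbinding rate |
| `b₀M` | 1 | s⁻¹ (per 10 codons) | monitor initiation rate |
| `R_total` | 2500 | nM | shared ribosome pool |
| monitor mRNA | 900 | nM | 30 nM plasmid × 30 transcripts/DNA |
| monitor length | 720 | bp | 24 sites |
| monitor γ | 1 | s⁻¹ (per 10 codons) | reference synthesis rate |
| promoter yields | 30 / 10 / 3 | mRNA per DNA | strong / medium / weak classes |
| assay | 30 + 20 | nM plasmid | monitor + test; the 50 nM saturation point |

These are the published simulation values, shipped verbatim in
`src/ribocap/params/default_params.json`. Two recorded inconsistencies are
left as printed: the back-calculation sketched for the pool size yields
≈2300 nM but the stated 2500 nM is used; and a weak promoter at 20 nM
plasmid gives 3 × 20 = 60 nM here, although 40 nM appears in the source
material — the per-DNA yields are treated as authoritative. Concentrations
are nM and time is seconds throughout; `b₀` and γ are per 10-codon step.

## Numerics

`solve_steady_state` root-solves `dy/dt = 0` on the concatenated occupancy
vector (scipy `hybr`) from an all-zeros initial guess, to an absolute
residual tolerance of 1e-9 on the largest time-derivative. A solution is
accepted only if all occupancies lie in [0, 1] and `R_free ≥ 0` (to 1e-7
slack); otherwise the system is relaxed by LSODA integration (time horizon
grown ×10 from 2×10³ s until the residual criterion is met) and polished
algebraically. The relaxation path can also be requested directly
(`method="relax"`) and serves as an independent oracle in the tests: on
randomized instances with up to 3 species and 30 sites, the two routes
agree to better than 1e-6 relative in every production rate. Conservation
holds exactly by construction; per-species flux balance (initiation flux =
every hop flux = release flux) holds to 10× the solver tolerance.

Degenerate inputs: a competitor with zero mRNA participates with zero
weight and leaves the monitor untouched; an empty competitor list
short-circuits to capacity 1.0 without solving.

## γ inference

Monitor capacity is strictly increasing in the competitor's γ, so the
inversion is Brent root-finding on log₁₀ γ over the bracket
[1e-4, 1e2] s⁻¹ (enclosing all observed values, which cluster in 0.1–3,
with wide margin), with the monitor-alone rate computed once per call.
The log-scale step tolerance (1e-6) makes the γ resolution far finer than
any measurement can support; convergence is declared when the achieved
capacity matches the measurement to a relative 1e-4.

Replicate capacities are averaged before inversion. Measurements outside
the model's achievable range raise by default, naming the achievable
interval; batch pipelines use the `clip` policy instead, returning the
bracket-edge γ flagged `converged=False` — under multiplicative noise a
construct imposing essentially no burden will routinely measure capacity
slightly above the supremum, and its γ is then genuinely unidentifiable
(only a lower bound is implied). When a capacity standard error is
supplied, the γ interval implied by ±1 s.e. is computed and the estimate
flagged `wide_interval` if it spans more than a factor of 10, which
happens wherever the capacity curve is nearly flat in γ (weak RBS, short
genes, or already-saturating γ).

Identifiability drives assay design: γ carries signal only where the
construct imposes measurable burden, which is why gene characterisation is
done in a strong-RBS (strength 2.6) test vector at 20 nM plasmid; weak-RBS
variants of the same gene are then *predicted*, not fitted.

## Plate-reader statistics

All windowed statistics share one convention: the rate at `t2` is the
finite difference between the samples nearest `t2 − 0.5 h` and
`t2 + 0.5 h`, divided by the actual time spanned. The half-window of 0.5 h
is the growth-rate definition, adopted identically for production rates so
that growth rate, per-OD production rate and absolute production rate at
the same `t2` are mutually consistent. No smoothing or blank subtraction
is applied before differencing (an optional blank-well subtraction,
`subtract_blank` / `--blank-sample`, exists but is off by default). OD700 is
preferred for growth when both OD channels are present.

* growth rate: `[ln OD(t3) − ln OD(t1)]/(t3 − t1)`;
* mid-exponential time: the admissible sample maximizing this windowed
  log-OD slope, with the first and last admissible windows excluded; a
  maximal slope below 0.01 h⁻¹ (doubling time ~3 days) raises a no-growth
  error;
* in vivo capacity: per-OD GFP production rate at mid-exponential;
* lysate capacity: the maximum absolute GFP production rate over all
  admissible windows (edges excluded) — max dGFP/dt;
* normalization: raw rate over the monitor-alone reference rate of the
  same plate and mode, making all capacities scale-invariant in the
  fluorescence units.

## Calibration and decomposition

The in vitro → in vivo map is an ordinary least squares line per
(strain, medium) condition, `y = a·x + b`, stored in a registry keyed by
condition label; prediction requires an explicit condition (no default).
Slopes increase with the condition's growth rate — burden expressed per
cell is milder in richer media. Predictions are clipped to [0, 1] with a
warning. Burden decomposition is exact arithmetic:
`expression = 1 − predicted_in_vivo`,
`metabolic = predicted_in_vivo − measured_in_vivo`; a negative metabolic
component (measurement above prediction) is allowed and flagged as
over-prediction.

## Synthetic data generator

The generator emulates the *statistical* structure of the assays with the
model supplying all ground truth:

* libraries sample γ log-uniformly on [0.1, 3] s⁻¹ (the observed range),
  RBS strength from {2.1, 2.6, 1.0, 0.5} (the two BCD-class strengths, the
  monitor reference, and a weak RBS), and length uniformly on
  [300, 3000] bp (short reporters up to long fusions); true in vitro
  capacities are computed with the model at the standard assay
  concentration;
* lysate traces are logistic GFP accumulations (rise, then plateau as the
  batch reaction exhausts itself), 5-min sampling over 8 h, scaled so the
  maximal 1-h-windowed rate equals truth × 2×10⁴ fluorescence/h;
* in vivo traces use an exponential-of-logistic OD curve — log-OD is
  sigmoidal, giving lag, exponential and stationary phases with the
  specific growth rate peaking at the 4 h midpoint (a plain logistic in OD
  has its log-slope maximal at t = 0 and no lag, which defeats a
  mid-exponential detector); GFP accumulates at truth × 10⁴ × OD(t) per
  hour, 10-min sampling over 10 h, and burdened wells grow proportionally
  more slowly;
* true in vivo capacity is linear in the in vitro value with
  condition-dependent slope — defaults (0.4, 0.35), (0.7, 0.19),
  (0.95, 0.05) for slow/reference/fast growth, the middle pair being the
  reference-condition relation — minus an optional additive metabolic
  penalty for active-pathway cohorts;
* noise is a single mean-one multiplicative log-normal factor per well
  (plate-reader and pipetting variation are amplitude-dominated), CV 0.05
  by default, three replicates per construct; one seeded generator is
  threaded through all stages, so a fixed seed reproduces every file
  byte-for-byte.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data: transcription-level competition, mRNA
degradation, resource depletion kinetics inside the lysate (only the
maximal rate carries signal), stress responses and adaptation, mutation or
escape, autofluorescence backgrounds, or model misspecification itself
(the "measured" capacities are generated by the same model family that is
fitted, so recovery tests measure inferential machinery, not biological
adequacy).

## Test problem sizes

Solver-equivalence and conservation suites use randomized instances of up
to 3 species × 30 sites; dosage-regime sweeps use 7 mRNA levels on
[0, 600] nM; round-trip grids cover γ ∈ [0.01, 10] at RBS
{0.5, 1.0, 2.6}; the end-to-end pipeline uses two cohorts of 12 constructs
× 3 replicates at default noise, one expression-only (calibration), one
with a 0.15 metabolic penalty (decomposition). These sizes give stable
medians while keeping the whole suite in the ten-second range.

## Known limitations

* γ is a lumped, context-free cost: re-using a γ across RBS contexts and
  operon positions assumes elongation cost is independent of initiation
  rate and neighbours.
* The model covers translation only; constructs whose burden is
  transcriptional (or whose promoters deviate from the three-class
  transcript-yield assumption) will be mispredicted in vitro.
* The in vitro → in vivo map is linear and per-condition; extrapolating a
  calibration across strains, media or growth phases is unsupported.
* Near-saturating capacities (>0.97 at the standard assay) identify only a
  lower bound on γ; the pipeline reports these as unconverged bracket-edge
  estimates rather than numbers to be trusted.
* Mean-field exclusion slightly misstates dense-traffic regimes compared
  with stochastic (TASEP) simulation, which is out of scope here.
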