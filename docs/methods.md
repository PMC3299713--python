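# Methods

`endosim` implements a stochastic population-based model of human embryonic
stem cell (hESC) differentiation during endoderm induction, together with the
analysis pipeline that uses it: candidate-mechanism simulation, parameter
sensitivity by histogram distance, a Monte-Carlo convergence study, ensemble
least-squares parameter estimation, and validation of population-dynamics
predictions.  This note records the model, its assumptions, the numerical and
design choices, and what the synthetic data do and do not establish.

## The cell-level model

Each simulated cell carries:

* a **signaling regime**, Ω (active: cycling, aging, differentiation) or A
  (dormant: fully frozen);
* an **affinity** `a > 0` governing regime residence.  `a` is drawn uniformly
  on (0, `a_0max`] at birth of the simulation, decays multiplicatively in Ω
  (`a ← a/d` per step, `d > 1`) and is unchanged in A.  The first time `a`
  falls below `a_min` the cell is permanently latched
  *proliferation-competent* and permanently loses the ability to enter A;
* an **age** against a uniform per-cell lifespan on [`l_min`, `l_max`]
  (death when exceeded; ages only advance in Ω), a **cycle position** in a
  fixed cell cycle of `t_cycle` hours whose first `t_g1` hours are G1, and a
  **proliferation window** (uniform on (0, `w_max`]) limiting how long a
  competent cell may keep dividing before senescence;
* per-lineage **propensity accumulators**.  In each G1 hour spent in Ω an
  uncommitted cell selects exactly one competing lineage with probability
  proportional to `propensity + ε` and increments it by `δ · nprog[lineage]`
  (`ε = δ = 0.01`; the tunable magnitudes are the `nprog` factors).  Crossing
  the stage threshold (`x_com`, stage 1; `x_com2`, stage 2) commits the cell
  irreversibly.

Regime transfers are attempted once per step with crowding of the destination
regime, `f(N) = 1/(1 + N/n_scale)`:

* Ω→A only during G1 and only while `a ≥ a_min`, with probability
  `min(1, aa · (a/a_0max) · f(N_A))`.  On entry the uncommitted propensities
  collapse to their arithmetic mean (dedifferentiation pressure);
* A→Ω with probability `min(1, (a_min/a) · f(N_Ω))` — low-affinity cells
  leave the dormant niche sooner.

Division occurs when the cycle position wraps while the cell is competent,
within its proliferation window, and of a phenotype the active mechanism
allows to proliferate.  Daughters inherit phenotype, stage, propensities and
affinity; age/cycle restart and lifespan/window are redrawn.

Two differentiation stages implement the mesendoderm hypothesis: stage-1 hESC
compete between mesendoderm and visceral endoderm; committing to mesendoderm
re-initializes the affinity (uniform on (0, `a_0max2`]), resets proliferation
competence, and opens a stage-2 race between definitive endoderm and
mesoderm.  Mechanism variants without the intermediate use a single-stage
race {definitive endoderm, visceral endoderm, mesoderm} directly from hESC;
their stage-2 parameters are inert.

The 12 candidate mechanisms are all combinations of: mesendoderm present or
absent (2) × CXCR4 expressed in mesoderm or not (2) × proliferation scope (3:
all phenotypes; endoderm and uncommitted; uncommitted only).  "Endoderm" in
the middle scope means definitive endoderm only — visceral endoderm is an
extra-embryonic phenotype and is excluded.  Marker read-out is
commitment-gated: Sox17+ = visceral + definitive endoderm; CXCR4+ =
definitive endoderm + mesendoderm (+ mesoderm iff the mechanism says so).

## Default parameters

Times in hours; affinity/propensity dimensionless.  `dt = 1`, horizon 120,
observations every 24 (days 0–5).

| parameter | default | meaning |
|---|---|---|
| `a_min` | 0.04 | affinity threshold: proliferation unlock / A-regime lockout |
| `a_0max`, `a_0max2` | 1.0, 0.5 | initial-affinity caps, stages 1 and 2 |
| `x_com`, `x_com2` | 0.1, 0.1 | commitment thresholds |
| `d` | 1.07 | per-hour affinity decay in Ω |
| `t_g1`, `t_cycle` | 10, 24 | G1 duration, cell-cycle length |
| `l_min`, `l_max` | 24, 130 | lifespan range |
| `w_max` | 120 | proliferation-window cap |
| `aa` | 0.4 | Ω→A transfer scale |
| `n_scale` | 100 | crowding scale of `f(N)`: the dormant niche saturates well below the population size |
| `nprog` stage 1 | ME 1.2, VE 0.6 (DE 0.9, MESO 0.9 single-stage) | propensity-update magnitudes |
| `nprog` stage 2 | DE 0.55, MESO 2.6 | |

The published analysis did not print its nominal values, so these were chosen
by hand so that the nominal Mechanism-B simulation qualitatively reproduces
the Condition-A calibration dynamics: commitment beginning during day 1, a
CXCR4 drop after day 2 driven by mesendoderm→mesoderm conversion, and a
retained uncommitted reservoir maintained by Ω↔A shuttling.  They are the
centers of the default ensemble sampling bounds (a factor of 10 either side,
with structural caps such as `t_g1 ≤ t_cycle`), and the nominal point of the
sensitivity analysis.  The `nprog` defaults deliberately avoid values for
which `x_com` is an exact multiple of the propensity increment: the
commitment comparison (`≥`) would then sit on a floating-point boundary and
different arithmetic paths could commit one update apart.

## Simulation engine

The production integrator is a numba-compiled per-cell loop
(`endosim._kernel`); cells interact only through the per-run regime census
taken at the start of each step, so per-cell evaluation order is immaterial.
A separate vectorized numpy implementation of the same rules serves as the
instrumented reference: `simulate(..., check_invariants=True)` runs it and
asserts, after every step, positive affinity, no A-residence below `a_min`,
no competent cell in A, uncommitted propensities strictly below threshold,
and the conservation identity
`live + cumulative_dead − total_divisions = n_initial` per run.  The two
paths consume random numbers in different orders and are therefore equal in
distribution, not bitwise; a cross-validation test holds their aggregated
outputs to Monte-Carlo agreement.  Each path is exactly reproducible under
its seed: all randomness derives from one `SeedSequence`, with runs batched
deterministically (the batch split depends only on the population size).
Replicate runs inside a batch share one stream; per-run parallelism is not
implemented.

Extinct runs simply stop contributing cells; their marker fractions are
reported as 0 with a logged warning, and conservation still holds.

## Synthetic calibration data

No public data accompany the study, so the pipeline fits generated curves
that encode the reported qualitative features for days 0–5:

* **Sox17+**: concave quadratic through 0 at day 0, peaking at 0.19 on day 3
  (Condition A: Activin A) or 0.23 on day 2 (Condition B: Activin A + FGF2 +
  BMP4), clipped below at 0 — for Condition B this makes days 4–5 exactly 0;
* **CXCR4+**: constant plateau (default 0.15) through day 2, an immediate
  drop (to 0.03 / 0.02), then a linear rise (slope 0.04 / 0.09 per day; the
  steeper slope is Condition B);
* **growth** (live count / day-4 value): Condition A declines until day 3
  (proliferation lag) then rises roughly linearly; Condition B does most of
  its growing before day 3;
* **cumulative death** / day-4 value: linear.

Optional measurement noise is per-point Gaussian, clipped to valid ranges,
with death kept nondecreasing and growth/death renormalized to 1 at day 4.

Two features of these curves are *not* reachable by any simulation that
starts from a pure hESC population: the nonzero CXCR4 plateau already at day
0, and Condition B's Sox17 values of exactly 0 at days 4–5 (committed
endoderm cannot vanish).  They act as an error floor shared by all
mechanisms.  Passing tests on these data therefore establish that the
pipeline behaves as designed on curves with the reported shapes — not that it
would reproduce every published contrast on the real flow-cytometry data; in
particular the large error separation reported between mechanisms with and
without mesendoderm does not emerge under these conditions (the minimum
errors of all mechanisms collapse into a narrow band dominated by the shared
floor), and the corresponding acceptance check documents this as a failure
rather than weakening the assertion.

## Sensitivity analysis

Each model scalar (including the `nprog` entries and the plumbing constants;
`dt` excluded, since scaling the integrator step changes the observation grid
itself) is perturbed by +10% one at a time.  For each of four outputs — day-5
live count, cumulative dead, Sox17+ and CXCR4+ fractions across stochastic
runs — the distance between nominal and perturbed histograms is

`S = Σ_i | n_i/|x| − p_i/|y| |`,

summed over the bins of the nominal histogram plus two explicit overflow bins
so no perturbed mass is dropped; `S` equals twice the total-variation
distance of the binned empirical distributions and is bounded by 2.  Bins
have the Freedman–Diaconis width `2·IQR·n^(−1/3)` (linear-interpolation
quantiles) and count `k = ceil(range/width)`, built from the nominal sample
only — the measure is deliberately asymmetric.  Nominal and perturbed
simulations share a seed (common random numbers), so a parameter the active
mechanism never reads scores exactly `S = 0`.  A degenerate nominal sample
(zero IQR) falls back to a single unit-width bin around the point mass.
Parameters are classified sensitive per output by the largest gap in the
sorted `S` values, mirroring the clear jump between low- and high-sensitivity
parameters; the published bin counts (37–51) and eight sensitive classes are
qualitative context, not assertions, since they depend on the unpublished
nominal values.

## Ensemble estimation and mechanism selection

Parameter vectors are sampled uniformly and independently per dimension from
the sensitive-parameter box; each is simulated and scored against the marker
dynamics only:

`E = (1/2T) Σ_days [(sox_sim − sox_obs)² + (cx_sim − cx_obs)²]`,

the mean of squared residuals over days (day 0 included) and the two marker
outputs on the 0–1 fraction scale — on this scale the published thresholds
(0.025/0.05/0.1) are meaningful.  The accepted ensemble is `E ≤ threshold`;
the best fit is the arg-min.  Growth and cumulative-death dynamics never
enter the fit; they are held out for verification, reported as the
mean-squared deviation of day-4-normalized curves.

The marker error cannot identify the unstained pools: a fit that parks much
of the population, undifferentiated, in the dormant A regime is
indistinguishable *by markers* from one that routes the same mass into
(CXCR4-negative) mesoderm.  The held-out growth/death curves separate them —
parked cells neither divide nor die.  Predictions about unstained populations
(the undifferentiated and mesendoderm validation dynamics) are therefore read
from the *verified* ensemble member: among accepted samples, the one with the
best held-out growth/death score (`validated_index_`).  Ranking and
acceptance continue to use the marker error alone.

Desk-scale defaults (500 samples × 100 runs × 1000 cells) keep a full fit
around ten minutes on one core; the published operating point
(10000 × 4000 × 9000) is available via the `paper` scale preset.  Mechanism
ranking runs one ensemble per candidate mechanism with independent child
seeds and reports minimum error, acceptance counts and verification scores.

## Convergence study

A two-dimensional grid over initial population size and number of runs
records the day-5 CXCR4+ mean and its run-to-run dispersion.  The converged
point is the lexicographically smallest grid point whose mean is within a
tolerance (default one percentage point) of the largest grid point's mean —
the reference point of the default grid is the published operating point
(9000 cells, 4000 runs).  The tolerance is this package's choice; no
criterion is stated in the source analysis.

## Validation proxies

For comparison with Oct4 and Brachyury expression (reported as percent of
maximum fold change), the undifferentiated (hESC) and mesendoderm mean
fraction series are each divided by their own maximum over days.  With the
nominal defaults under Mechanism B the undifferentiated fraction decays to a
small plateau sustained by dormant-regime shuttling, and the mesendoderm
series is unimodal with an early interior maximum; the absolute plateau level
of the undifferentiated pool, however, is not identified by the calibration
curves (see above), so only the qualitative shape carries over to fitted
ensembles.

### Identifiability of the unstained pools

The calibration curves constrain the stained fractions (Sox17+, CXCR4+) and,
through verification, the growth/death shapes — but not the split of the
unstained remainder between retained undifferentiated cells and
CXCR4-negative mesoderm.  Dense ensembles on these curves accept parameter
sets whose day-5 undifferentiated fraction ranges essentially from 0 to 1 at
nearly equal marker error and verification score.  The undifferentiated-
population prediction reported by `scripts/acceptance.py` is therefore the
verified ensemble member's value under a fixed seed and should be read as one
member of a broad ensemble, not an identified quantity; identifying it would
require quantitative marker levels (not just curve shapes) or direct
undifferentiated-marker data in the fit.

## Known limitations

* No spatial structure, no cell–cell signaling, no ectoderm lineage, no
  graded marker expression; fixed-step (1 h) updating rather than
  continuous-time scheduling.
* The exact transfer-probability forms of the predecessor hematopoietic model
  are not restated in the source; only their qualitative contracts (monotone
  in affinity, crowding in the destination count, G1 gating, no A-entry
  below threshold) are preserved here, with the concrete forms above.
* Best-fit parameter values are not comparable to the unpublished published
  ones; only trajectory-level behavior is.
* The compiled kernel and the checked reference are distribution-equal, not
  bitwise-equal; seeds reproduce results only within one path.
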