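# Methods

## The titration model

A mother cell of volume M (µm³) committed to division enters S/M carrying a
regulator stock

    A(M) = a · M^b        (AU),   A = 0 below the commitment size

and executes division rounds r = 1, 2, … During round r the nuclei double
(2^r nuclei after r rounds, one genome copy each) and the stock is depleted:

* geometric mode (default): A ← A·(1 − δ);
* linear mode: A ← A − δ·A₀, clipped at zero, where A₀ is the initial
  stock. The linear decrement is tied to δ so the parameter set stays
  minimal; it exists because measured stage means of nuclear concentration
  are also well described by a straight line.

Three observables follow from the state: per-nucleus amount A/2^r, per-DNA
ratio A/2^r (one genome per nucleus), and nuclear concentration A/V_nuc,
where the total nuclear volume V_nuc is constant during S/M (nuclear volume
halves as nuclei double; default V_nuc = 0.1·M from the constant N/C
ratio). In geometric mode the per-round factors are exactly (1 − δ) for
concentration and (1 − δ)/2 for the per-DNA ratio — a ≥ 2-fold drop per
round for any δ ≥ 0.

Round r ≥ 2 starts only if the sensed quantity, evaluated on the state the
previous round left, is at or above the exit threshold θ. Committed mothers
always complete round 1 (commitment guarantees at least one division even
without further growth). Which of the three quantities is sensed is
genuinely open — dilution and turnover cannot be separated on current
evidence — so all three are selectable (`sensed_quantity`), with the
per-DNA ratio as the default since a ratiometric signal against genome
copies is the natural counting variable. With the defaults the number of
rounds is

    n(M) = clip( 1 + ⌊ log(a·M^b/θ) / log(2/(1−δ)) ⌋ , 1, max_rounds ),

monotone in M: the sizer. `max_rounds = 5` guards against runaway
parameterizations (observed mothers divide at most four times).

### Defaults and calibration

| parameter | default | units | rationale |
|---|---|---|---|
| a (production_coeff) | 1.0 | AU·µm⁻³ᵇ | scale is arbitrary; a and θ are exactly degenerate in division counts, so a is the fixed gauge |
| b (production_exponent) | 1.5 | — | minimal allometric form: concentration grows as M^0.5, matching the equal-protein-load observation that larger mothers have more regulator per biomass |
| θ (exit_threshold) | 2000 | AU/genome | calibrated once so that just-committed cells (~200 µm³) divide once, ~350 µm³ mothers twice, ~600 µm³ mothers three times and ~800 µm³ four — the dark-shift population behaviour — and 600/2³ = 75 µm³ reproduces the wild-type daughter size |
| δ (degradation_fraction) | 0.1 | /round | "small but significant" net loss; magnitude is not quantified by measurement, so it is a tunable default |
| commitment_size | 195 | µm³ | measured wild-type commitment size |
| null_exit_threshold | 220 | µm³ | backup sizer for the loss-of-function scenario (below) |
| max_rounds | 5 | — | safety cap |

The calibration was chosen from these anchors before use and is not
adjusted per experiment.

### Genotype scenarios

* **wild_type** — the base parameters.
* **cdkg1_null** — production set to zero. Cells still divide (commitment
  is upstream and intact) but exit early: other, unidentified mechanisms
  terminate S/M prematurely. This backup is modelled as the simplest
  mechanism that reproduces "fewer divisions, larger daughters": a size
  threshold on the per-nucleus cell volume M/2^(r−1) sensed before each
  round (default 220 µm³). Any mother that would divide three times under
  the wild-type defaults divides strictly fewer times here.
* **overexpression** — a constitutive supplement (default 800 AU per
  nucleus per round) is added to the stock every round, as from a
  constitutive promoter that keeps producing during S/M; the per-DNA decay
  flattens and extra rounds run, giving smaller daughters. The supplement
  keeps the fixed point of the per-DNA recursion (s/(1 − (1−δ)/2) ≈ 1455)
  below θ, so division still terminates rather than hitting the cap for
  typical mothers.

### Unit accounting

The discrete variant books one unit per mitosis: round k costs 2^(k−1)
units, cumulatively 2^n − 1 for n rounds, so U units afford
n = ⌊log₂(U+1)⌋ rounds. `run_division_series` reproduces this exactly in
`unit_mode` (threshold 1 AU per nucleus); in this mode the ledger alone
decides and the committed-divide-once rule is waived, since zero units must
mean zero rounds for the arithmetic to hold at U = 0.

## Population simulation

Daughters grow exponentially in volume, 2^(t/T) with size-doubling time
T = 4 h, stopping at a dark shift; cell-to-cell variability is unit-mean
lognormal (CV 0.15 by default). Growth is the standard minimal model — only
doubling times and fold-growth are constrained by observation. Commitment
is a volume flag at the commitment size. Division is exactly equal
(uniform daughters); unequal cleavage is out of scope. An optional
lognormal jitter on θ per cell (`threshold_noise_cv`) models sizer
sloppiness; daughter-size spread widens monotonically with it.

The packaged dark-shift design splits one synchronized culture into a
pre-commitment control (dark shift at 3 h; median ~80 µm³), small mothers
(7 h; ~350 µm³) and large mothers (full 14 h light; ~600 µm³). The target
medians are config defaults applied directly (the measured culture
doubling time of ~5.9 h does not map 75 µm³ daughters onto those medians
with pure exponential growth, reflecting non-exponential lag/settling that
this package does not model). Regulator content per population is reported
per biomass (Σ amounts / Σ volume — the equal-protein-load gel analog) and
per cell (Σ amounts / N — the equal-cell-number analog).

## Image quantitation

Nuclear segmentation is a global Otsu threshold on the DAPI channel with
8-connected labeling and a minimum-area filter (1 µm² default) — a
reproducible stand-in for interactive tracing. Z-stacks are reduced by
maximum projection. Background is a single scalar per image (mean of an
untagged-control image); per-pixel signal is clipped at zero after
subtraction. Per-nucleus intensity is the background-subtracted sum over
the nucleus's pixels; area converts to volume with the projected-area
sphere formula V = 4/3·(A/π)^{3/2} (the `corrected=True` variant multiplies
by π for the true sphere volume — the constant cancels in every relative
quantity, so the π-less form is the default convention); concentration is
intensity/volume. A cell's per-DNA ratio is its summed nuclear intensity
divided by its nuclei count; its nuclear fraction is nuclear/total signal,
with a strict >0.5 rule for "majority nuclear" scoring.

Stage summaries include only cells whose mother size predicts at least
three divisions (so stages within one size cohort are compared) and flag
stages with fewer than 68 cells, the study's per-stage minimum. The
"non-parametric two-tailed t test" between stage groups is read as the
Mann–Whitney rank-sum test — the conventional interpretation; a permutation
t-test is the plausible alternative and is not implemented as the default.
Small samples are tested exactly (full enumeration; with ties, an exact
permutation test; two-sided p is twice the smaller inclusive tail, capped
at 1), larger ones with the tie-corrected normal approximation. N/C groups
use a one-way ANOVA; all-constant degenerate input returns F = 0, p = 1
when means agree. Stage-mean linearity is ordinary least squares of mean
concentration on stage index.

## Synthetic data

Generators are pure functions of (config, seed) and always emit ground
truth. Defaults encode the study conditions: daughter volumes lognormal
with mean 75 µm³ and CV 0.04 (75 ± 3); stages 1, 2, 4, 8, 16 nuclei with
stage-1 nuclear radius 2.5 µm shrinking as s^(−1/3), keeping total nuclear
volume constant (checked to 1e−9 relative); a geometric concentration
schedule c₀(1−δ)^k with c₀ = 50 AU/µm³ and δ = 0.1 (or the linear analog);
N/C ratio 0.1; multiplicative lognormal measurement noise with CV 0.1 on
intensities and geometry, additive Gaussian noise on pixels. Rendered
images place nuclei as filled disks on a jittered grid (non-overlap by
construction), with the disk sum exactly equal to the record's intensity
and any cytoplasmic fraction spread uniformly over the cell mask. The
images have no point-spread function, photobleaching or z-attenuation;
passing recovery tests therefore demonstrates correctness of the
measurement arithmetic and statistics, not robustness to optics.

`gen_division_observations` builds the parameter-recovery cohort: 500
mothers log-uniform over 200–1000 µm³, division counts from the model,
and per-round nuclear concentrations observed with CV-0.1 multiplicative
noise. Mother volumes and division counts are taken as observed directly —
electronic volume sensing and division scoring are far more precise than
fluorescence intensities, which is where the measurement noise lives.

## Parameter recovery

`fit_params` grid-searches (θ, δ, b) with two rounds of local grid
refinement, minimizing squared error in n_rounds plus two trajectory
terms: (i) per-stage geometric means of per-cell-normalized concentrations
(log-linear in k with slope log(1−δ) — geometric means of within-cell
ratios are unbiased in log space and immune to the cohort-composition
shift from larger mothers reaching later stages), and (ii) per-cell
first-round concentration against mother volume, whose log-log slope is
b − 1 at fixed N/C. Without the trajectory terms the three parameters are
confounded (division counts constrain only b/L and log(a/θ)/L with
L = log(2/(1−δ))); the degeneracy is flagged in the diagnostics rather
than silently resolved. The production coefficient a is fixed by the base
parameters — a and θ are exactly degenerate in counts, so one must be the
gauge. Under the default cohort the three parameters are recovered within
10% relative error; the binding precision limit is δ, whose estimate
inherits the noise of the stage-mean decay.

## Numerical conventions and limitations

Pixel coordinates are 0-based, row-major, y-down; areas are pixel counts ×
pixel_size². Closed-form round counts use a 1e−9 guard inside the floor to
avoid spurious boundary flips; agreement with the iterative series is
property-tested. Degenerate inputs (empty populations, all-background
images, zero-signal cells, constant ANOVA groups) follow the rules stated
in the docstrings. The simulator has no cell death, no light-quality
effects and no timing kinetics beyond the light/dark structure; the
within-population variance of division number at fixed mother size is not
constrained by measurement and enters only through the optional threshold
noise. Problem sizes in the test suite and acceptance script (hundreds of
cells, 100 ANOVA replicates, one 500-cell recovery cohort) were chosen as
the smallest sizes at which the statistical claims are stable across
seeds.
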