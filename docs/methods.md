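# Methods

`flptpm` simulates and analyzes tethered-particle-motion (TPM) experiments on
Flp site-specific recombination. A 1168 bp DNA tether carrying zero, one or
two *FRT* sites anchors a reporter bead; the bead's restricted Brownian motion
(BM) amplitude reports the effective tether length, which shrinks when
recombinase bends a bound site, shrinks further when two bound sites synapse,
and — after an SDS quench strips all non-covalent contacts — reveals whether
covalent strand exchange occurred. This note describes the model, the
synthetic-data generator, the analysis pipeline, and the numerical and design
choices a user should know about.

## Kinetic model

One molecule is a continuous-time stochastic process over the states

```
FREE  <->  NONPRODUCTIVE
FREE   ->  PRESYNAPTIC  ->  SYNAPSED_WAYWARD  (type a; reverts to PRESYNAPTIC)
                        ->  SYNAPSED_ACTIVE   (type b)
SYNAPSED_ACTIVE -> HOLLIDAY_OR_PRODUCT (HJ -> resolved)   [irreversible]
```

Association out of `FREE` is a competing-risks race between two
pseudo-first-order channels, `k_f_np*[Flp]` into the non-productive complex
(bound sites that never synapse stably; decays back at `k_d_np`) and
`k_f_ps*[Flp]` into the pre-synaptic complex. A pre-synaptic episode is an
*outcome-labelled mixture*: the outcome (wayward, probability `1 - p_type_b`;
active otherwise) is drawn first and the dwell is then exponential with that
outcome's own rate (`k_f_wayward`, `k_f_synaptic`). This parameterization —
rather than competing risks with a shared total rate — is the one under which
the pooled type-a and type-b dwell sets have *distinct* single-exponential
rates, which is how the two synapse-formation rates are defined and measured.
Wayward synapses dissociate back to the pre-synaptic state at `k_d_wayward`;
active synapses proceed through chemistry irreversibly, and nothing leaves
`HOLLIDAY_OR_PRODUCT` before the quench.

Default rate constants (SI units) are the fitted values for Flpe on direct
*FRT* sites, Flpe on inverted sites, and the cleavage-dead Flpe(Y343F) on
direct sites; `default_scheme(variant, orientation)` returns them and
`KineticScheme.to_yaml` round-trips them through config files. For Y343F,
`k_r = 0` by construction. For inverted sites the two pre-synaptic outcome
rates were not separately measurable and both default to the single pooled
synapse-formation rate, with `p_type_b = 0.15` taken from the amplitude split
of the bi-exponential synapsed-dwell decay.

**The chemistry clock.** The headline recombination constant
`k_r = 1.7e-3 s^-1` (slow component of the inverted-site synapsed decay) is
too slow to explain >90% covalent commitment of direct-site synapses within
10 minutes; first-strand chemistry must be faster than the full conversion.
The simulator therefore exposes two configurable internal rates,
`k_first_chem` (active synapse -> covalent Holliday junction) and
`k_hj_resolve` (junction -> resolved product), both defaulting to `10*k_r`:
junction formation is the rate-limiting chemical step and resolution is not
slow. This is a deliberate, adjustable modeling choice, not a measured pair
of constants; consequences: (i) direct-site endpoint fractions come out at
~0.9-1.0, matching the observed commitment, and (ii) the simulated
inverted-site slow exit from the low-amplitude state is hypoexponential with
an effective rate nearer `8e-3 s^-1` than `k_r`. Users who want the printed
slow component in end-to-end inverted simulations should set `k_first_chem`
accordingly.

## Emission model (what the generator emulates)

Each state maps to a mean BM amplitude from the per-substrate amplitude
ladder (e.g. direct sites: free 82.3 nm, bound 59.2 nm, synapsed 42.0 nm;
post-SDS low level 45.1 nm, the short linear excision product). Bead
positions are drawn per frame (29.85 Hz, i.e. 200 frames ~ 6.7 s), per axis,
as independent zero-mean Gaussians with `sigma = mu_eff/sqrt(2)`, so the
windowed BM statistic below is an unbiased estimator of `mu_eff` by
construction — emission and estimator are a coupled convention.

The tabulated `mean ± spread` values are widths of *pooled* BM histograms,
which already contain the 40-frame estimator sampling noise
(`~mu/sqrt(160)`); treating them wholly as molecule-to-molecule variability
would double-count noise. The generator therefore derives the
between-molecule spread by variance subtraction (floored at zero) and draws
*one* standard-normal deviate per molecule, scaled per state, so a molecule
keeps a consistent amplitude bias across states. Pooled simulated histograms
then reproduce the tabulated widths. For inverted sites the resolved
(post-recombination) sub-state emits the parental high amplitude before SDS
— the inversion product is full length — which is what produces the slow
low-to-high exits of the bi-exponential signature; the unresolved junction
stays low and maps to the low post-SDS level.

What the generator does **not** emulate: bead-tether polymer physics,
excluded volume, tracking drift, camera blur, or localization error. Passing
tests therefore demonstrate that the *analysis* recovers the *model*; they
cannot certify performance on real bead data whose noise is not Gaussian or
not white. Two artifact classes are injected on request to exercise the QC
filters: stuck-bead intervals (amplitude collapsed to ~10 nm) and
axis-distortion intervals (x scaled 1.5x). An optional transient
non-specific binding channel exists but is off (rate 0) by default.

## Trace analysis

**BM amplitude.** Non-overlapping 40-frame windows;
`BM = sqrt(s_x^2 + s_y^2)` with Bessel-corrected per-axis standard
deviations (the Bessel correction makes `BM^2` unbiased at finite window
size; the residual chi-type bias of BM itself is ~0.3%). The series is
smoothed by a five-point adjacent average whose window shrinks symmetrically
(1, 3, 5, ... points) at the edges, leaving endpoints unbiased.

**QC filters.** (i) Stuck bead: any run of more than 5 consecutive smoothed
points below 26 nm (5 points = 200 frames ~ 6.7 s). (ii) Distorted motion:
pooled sd_x/sd_y per 200-frame block outside 0.8-1.2 for at least 3
consecutive blocks. The block size keeps the ratio's sampling noise (~7%)
well inside the band, so clean molecules are essentially never flagged
(single 40-frame windows have ~16% ratio noise and would flag everything);
requiring ~20 s of sustained anisotropy is the point of the filter.
(iii) Length criterion: two-sided z-test of the pre-addition baseline mean
against the substrate's nominal amplitude at P < 0.05, with the ~150 bp
length resolution converted to nm by the two-anchor length calibration
(1168 bp -> 83.4 nm, 549 bp -> 45.1 nm) as the SD proxy.

**Level calling.** Threshold idealization against the per-substrate ladder
with midpoint thresholds (ties to the lower level) and a three-point
persistence floor, plus three robustness elements that field experience with
threshold idealizers motivates:

* *Baseline calibration.* Each molecule's ladder is shifted to its own
  protein-free baseline (bias expressed as a z-score of the top level's
  between-molecule spread, propagated per level through each level's own
  spread and clamped so the ladder stays ordered). Raises frame accuracy
  from ~94% to ~99.5% under default noise.
* *Unsmoothed input.* Level calling uses the raw windowed series: windows
  are statistically independent, so persistence controls false transitions,
  whereas five-point smoothing attenuates 3-4-window state visits below
  detectability and merges the flanking dwells (QC and the post-SDS endpoint
  call still use the smoothed series).
* *Run significance.* A run sandwiched between runs of one other level is
  kept only if its mean sits on its own side of the midpoint by >= 2 SE of
  the run mean (point noise `mu/sqrt(160)`). Genuine excursions spend full
  amplitude at their level and pass overwhelmingly; threshold-grazing noise
  runs — which would split long-lived phases into spurious dwells of
  hundreds of seconds — are absorbed.

Molecules whose calibrated bound-synapsed gap falls below
`min(3 sigma_BM, 0.6 * nominal gap)` are excluded as unresolvable (~4% of
direct-site molecules; the nominal-gap floor keeps the intrinsically narrow
inverted ladder analyzable). Dwell extraction reads association,
non-productive, pre-synaptic (type a/b by the ensuing synapse's fate) and
synapsed dwells off the idealized runs, clips them to the
addition-to-quench window, and flags quench-truncated dwells censored;
censored dwells are excluded from fits by default. Classification follows
the complex taxonomy with the orientation-aware endpoint logic: for
inverted sites a synapsed molecule restored to high amplitude by SDS is
`ambiguous` (completed inversion and wayward complexes are per-molecule
indistinguishable; the split is statistical, via the bi-exponential dwell
analysis — deliberately never resolved per molecule).

## Dwell-time fitting

Public decay fits operate on histogram counts: right-open bins from zero
with default width `max(2 s, range/25)` (pass an explicit width, e.g. 10 s,
for strongly bimodal mixtures whose fast component would otherwise collapse
into one bin). `fit_single_exponential` is unweighted nonlinear least
squares; `fit_biexponential` adds multi-start initialization (rate pairs
bracketing the single-exponential estimate by 5x) and then polishes with a
binned Poisson likelihood — unweighted least squares is nearly blind to the
sparse tail bins that carry all the slow-component information (slow-rate
scatter drops ~6-fold on mixture data). Both report asymptotic standard
errors, an unweighted R^2, and a Poisson-weighted R^2. Model selection — the
operational form of the irreversibility test — accepts the bi-exponential
only if it improves the *weighted* R^2 by >= 0.03, separates the rates
3-fold, and gives both components >= 5% of the dwells; unweighted R^2
saturates near 1 for any single decaying component and cannot discriminate
(the weighted statistic reproduces the characteristic ~0.91 vs ~1.00
contrast on mixture data). On data truly from one exponential the
two-component model is selected in <5% of replicates; on the
85/15 mixture of 1.7e-2 and 1.7e-3 s^-1 it is selected in >95%.

`compile_kinetic_table` turns a cohort's dwell pools into the per-complex
rate table. Because threshold idealization at 40-frame resolution cannot see
state visits shorter than ~3.5 windows (4.7 s), the estimator layer differs
from the display layer in two ways, both package design choices:

* rates come from the truncated-mean (shifted-exponential tail) MLE with an
  8 s trim — the maximum-likelihood analogue of fitting only the histogram
  tail, and about twice as efficient as histogram least squares at
  per-transition pool sizes (~150 dwells per cohort);
* first-order missed-event corrections undo the merge biases that
  invisible short visits cause: free and non-productive dwell means are
  deflated for invisibly short intervening visits, pre-synaptic dwells for
  invisibly prepended non-productive visits, and the non-productive
  association count is inflated for undetected and merged visits before the
  destination split. The two association channels are separated by the
  competing-risks decomposition — pooled exit rate times corrected
  destination fractions — because under a competing-risks race both
  destination-specific dwell pools share the same total exit rate and
  fitting them separately cannot distinguish the channels.

With these estimators a 500-molecule, 30-minute direct-site cohort recovers
all six pre-chemical rate constants with biases <= ~6%; the binding
statistical limit is the wayward pool (~170 dwells), whose ground-truth
mean itself fluctuates by ~8% SD across cohorts, so individual cohorts can
land outside a 15% band on `k_d_wayward` by ordinary sampling variation.
The corrections assume pipeline-measured pools; for dwell sets constructed
without a detection floor, set `FitConfig(missed_event_correction=False)`.
For inverted cohorts under the default chemistry clock the synapsed mixture's
rate ratio (~2) is below bi-exponential resolvability and the table falls
back to a single-exponential wayward decay; the inverted association split
also carries ~20% systematic error from destination mislabeling across
invisible free gaps. Direct-site cohorts are the quantitative target;
inverted end-to-end numbers are qualitative.

## Reproducibility and problem sizes

Every stochastic routine takes a seeded NumPy generator; cohorts spawn
independent per-molecule substreams from one root `SeedSequence`, so results
are reproducible and byte-identical under a fixed seed regardless of
ordering. Default analysis problem sizes — 10^4 dwells for distribution
fits, 40-120 molecule cohorts for QC/classification properties, 500
molecules for full rate recovery — were chosen so each check sits well
inside its statistical tolerance while a complete run stays interactive on
one CPU.

## Known limitations

* Gaussian, white, isotropic emission noise; no drift or tracking error.
* The paper-level tension between the printed association-constant ratio
  (which implies ~75% of first bindings are non-productive under competing
  risks) and the reported ~3%/97% complex split is left as-is; the package
  recovers the constants it simulates from, and reports the bound-level
  occupancy (share of recombinase-bound time at the bound vs synapsed
  level) as the population-level "non-productive fraction" statistic, since
  under the printed rates every molecule synapses at least once in 30 min
  and a per-molecule never-synapsed count cannot show the effect.
* Dwell durations are quantized to the 1.34 s window grid; dwells under
  ~5 s are unobservable and handled by correction, not detection.
* No hidden-Markov or Bayesian idealization; the threshold scheme is chosen
  for auditability and because the analysis it reimplements is
  threshold-based.
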