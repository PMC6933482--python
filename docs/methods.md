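# Methods

This note documents the models, defaults, and design choices behind
`nfloop`, and what its synthetic-data validation does and does not show.

## Run timing

A training run is described by an `AcquisitionSpec` (TR = 1.5 s, 10 dummy
scans, 150 scans total) and a `BlockDesign`: dummies, then four 30-s
baseline and three 30-s regulation blocks alternating B R B R B R B.
This yields a 225-s (3.75-min) run with 140 analyzed scans and 60
regulation scans. The faces/houses localizer uses seven 30-s stimulation
blocks (F H F H F H F) in a 166-volume run (4.15 min). The nominal 21-s
rest gaps between stimulation blocks do not fit a 166-volume budget
(7×30 s + 6×21 s + 15 s of dummies = 336 s > 249 s), so the builder treats
the volume total as authoritative: gaps shrink to the 2 scans the budget
allows and the 4 residual scans are appended as terminal rest. An override
flag builds other totals, e.g. with full 14-scan gaps.

## Hemodynamic response

The canonical double-gamma HRF (6-s peak, 16-s undershoot, peak/undershoot
ratio 6, 32-s support; `nilearn`'s SPM variant) is sampled at TR and
normalized to unit sum, so a sustained convolved boxcar plateaus at 1 and a
planted gain is read directly in percent of baseline.

## Synthetic BOLD model

Each ROI's run is

    y(t) = baseline · (1 + gain · (boxcar_regulate ⊛ HRF)(t) / 100)
         + drift · t + AR(1)(t) + spikes(t)

with defaults chosen to sit where single-ROI neurofeedback data sit:
baseline 1000 a.u. (so percent-signal changes land on the 0.1–0.4% scale),
AR coefficient 0.3, stationary noise SD 5 a.u. (0.5% of baseline), drift
0.01 a.u./scan, and one-sided positive spikes of 30 a.u. at probability
0.01 per scan (motion/swallowing artifacts push the signal up, which is
what the online despiking rule targets). Demo group gains are 0.28%
(contingent ASD group), 0.20% (contingent control), 0 (sham control) —
configurable scenario parameters, not ground truth about any population.
Network runs draw AR(1) innovations mixed through the symmetric square
root of a target correlation matrix; because all regions share the AR
coefficient, the planted correlation survives the recursion. Every
generator is a pure function of (parameters, seed).

What the generator does **not** emulate: spatial autocorrelation and
motion-induced spatial artifacts, physiological (cardiac/respiratory)
noise, multi-echo/multi-coil effects, field inhomogeneity, and
inter-subject anatomical variability. Passing tests therefore validate
the *machinery* — estimators recover what was planted under this noise
model — not any empirical claim about real participants.

## Online feedback

`F = (window − base)_ROI1 − (window − base)_ROI2` per regulation scan,
where the window is the last min(3, elapsed) accepted scans *of the
current regulation block* (the window grows 1→3 at block start), the
baseline is the mean of the entire preceding baseline block (a trim
parameter can drop initial transition scans; default 0), and ROI1 is the
unweighted average of the left and right patch means. Both feedback and
reference ROIs are despiked by default (a flag disables the reference).

Despiking accepts an incoming sample unless it exceeds the median of the
last m = 3 accepted samples by more than k = 3 robust SDs, in which case
the mean of those samples is substituted. The robust SD is 1.4826·MAD
with a floor of 0.1% of the signal level: a raw MAD of a near-constant
window is 0, which would reject ordinary noise; the floor (well under the
noise floor of raw BOLD at ~1000 a.u.) keeps the rule sensitive only to
genuinely abrupt jumps. The rule is one-sided (increases only) by
default. Consequences: the streaming computation and a batch replay of
the same rule agree bit-for-bit; adding a common offset time series to
all ROIs cancels exactly as long as no despike replacement fires (a
replacement substitutes past values, breaking exact cancellation by
construction).

The thermometer maps F = 0 to the center of 10 bars at 1 a.u. (0.1% of a
1000-a.u. baseline) per bar, clamped to [0, 10] — purely presentational,
stored for provenance. Sham feedback is a reflected Gaussian random walk
on the feedback scale (step SD 1 a.u., bounds ± half the thermometer
span), a function of (seed, length, config) only.

## Up-regulation metrics

`rffa` is the percent signal change of regulation over baseline samples.
Block windows are shifted by 3 scans (4.5 s) by default: the quantity is a
hemodynamic response, and with no lag the rise/decay transients leak
across block edges — a noiseless planted 0.3% gain reads 0.2097% at shift
0 (30% low) but 0.2861% at shift 3 (4.6% low), the shift sitting inside
the 4–6 s delay participants are themselves instructed about. The shift is
configurable for sensitivity analyses.

Within-run variability (SD-r_FFA) defaults to the SD of the three
per-regulation-block r values, each computed against the run's pooled
baseline; an alternative definition (SD of the raw BOLD over the run in
percent of baseline) is available by flag, since both readings of
"variability of the BOLD magnitude per run" are defensible.

Session deltas require both sessions (subjects with one session are
excluded with a warning); learning slopes are Spearman correlations of
group-mean r_FFA against run index with exact permutation p.

## Statistics

* Normality gate: D'Agostino–Pearson omnibus K² at α = 0.05, defined for
  n ≥ 8; smaller samples skip the gate, go nonparametric, and are flagged.
* One-sample location: t-test when normal, else Wilcoxon signed-rank
  (exact for n < 25 without zeros).
* Omnibus: one-way ANOVA + Tukey HSD when all groups pass the gate, else
  Kruskal–Wallis + Dunn's rank post-hoc (tie-corrected z statistics,
  Bonferroni-adjusted p; written in-package since no installed library
  provides Dunn's test).
* Mann–Whitney U: exact two-tailed p by enumerating every C(n1+n2, n1)
  rank arrangement (ties handled by enumerating the observed tied rank
  vector); falls back to the asymptotic p above 10⁶ arrangements, with
  the method recorded in the result.
* Spearman ρ: exact permutation p for n ≤ 10 (all n! pairings, chunked);
  t approximation beyond, recorded. Constant input yields an explicit
  "undefined" flag, never a silent 0.
* All p two-tailed unless an operation states otherwise; every result
  records which branch actually ran.

## Connectivity

Denoising order: two-sided rolling-median despike (clamp at 3 robust SDs —
unlike the one-sided online rule, offline artifacts can deflect either
way) → linear detrend → confound regression (confounds detrended
identically first) → zero-phase second-order Butterworth band-pass at
0.008–0.09 Hz. Correlations are computed per run on regulation-block
samples, mean-centered within the restricted support (the normalized
inner product is then the ordinary product-moment correlation — without
centering it would be a cosine, not a correlation), Fisher-z transformed,
and averaged across runs rather than concatenated, avoiding spurious
between-run covariance. Inference per seed: one-sample t on the across-run
z values, one-sided (positive), Benjamini–Hochberg FDR across that seed's
targets at q = 0.01. Subnetwork strength comparisons restrict to a
configured label set (default: a ventral-visual-stream list) and delegate
to the gated omnibus comparison.

## Group GLM

First level: per-voxel OLS (via `nilearn`'s mass-univariate fitter) with
HRF-convolved regulation and baseline regressors, intercept, and optional
six motion confounds; contrast regulate − baseline. Second level:
voxelwise one-sample t across subjects, one-sided voxel threshold
p < 0.001, family-wise correction by Bonferroni over in-mask voxels
(labelled "Bonferroni-FWE" in the provenance — random-field theory is out
of scope, so the map is conservative), and removal of clusters below
K = 10 voxels under 6-connectivity (conservative and deterministic).
Spatial smoothing is an explicit separable-Gaussian step (FWHM in mm,
truncated at 4 SD), never an implicit part of a fit.

## Pipeline

The pipeline is a pure function of (config, master seed). Per-subject and
per-run seeds derive from the master seed by SHA-256 (`stable_seed`),
keeping streams independent and below 2³¹. Every stage writes a JSON
provenance sidecar (config hash, seed, package version); rerunning a
config reproduces byte-identical tables. Series TSVs are written with
shortest-repr floats and read with round-trip parsing, so the on-disk
dataset round-trips bit-for-bit.

## Problem sizes used in validation

The test suite exercises desk-scale versions of every analysis: grids up
to 16×16×6 voxels, 8 runs × 60 regulation scans for connectivity
recovery, 50-run averages for effect recovery, 1000-replicate Monte Carlo
for test calibration, and 100-replicate recovery rates for ROI selection.
These sizes make every property measurable with tight Monte Carlo error
while the full suite stays fast; all scale parameters are plain arguments,
so larger reproductions are one-line changes.

## Known limitations

* The feedback loop models the 1.5-s update cadence but no acquisition or
  display latency, and no scanner transport protocol.
* ROI selection searches config-supplied boxes; there is no registration,
  atlas lookup, or anatomy.
* Bonferroni FWE is stricter than random-field FWE; cluster-level
  inference is extent-only.
* Exact tests enumerate; for samples far beyond the sizes this package
  targets the recorded fallback approximations apply.
* Group-level findings from any real experiment of this design depend on
  raw participant data; this package validates machinery on synthetic
  ground truth and makes no empirical claims.
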