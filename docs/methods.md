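# Methods

## The measurement this package models

Two chimeric protease probes report apoptotic signaling in single cells.
Each probe links a fluorescent-protein donor to an organic-dye acceptor via
a caspase-cleavable peptide: intact probes transfer excitation energy to
the acceptor (FRET), cleaved probes do not. The donor/acceptor intensity
ratio therefore rises as the target protease cleaves the probe pool. The
caspase-9 probe pairs GFP with Alexa Fluor 532, the caspase-3 probe pairs
RFP with Alexa Fluor 660; all four fluorophores are excited together and
read out through four detection bands (460–510, 520–550, 575–620,
655–755 nm) every 20 s. Each band collects leakage from the other
fluorophores, so per-fluorophore abundances are recovered by linear
spectral unmixing before ratios are formed.

The analysis chain is: ROI mean intensities (or per-cell trace tables) →
linear unmixing → donor/acceptor ratio per probe → normalization to
initial values → per-cell kinetic indices → population statistics.

## Trajectory model and the synthetic population

The generator is first-class code, not a fixture: it defines the study
conditions under which every accuracy claim in the test suite is measured.

Per cell and per probe, the normalized ratio is modeled as

```
R(t) = 1                                   t < t_init   (baseline)
R(t) = 1 + scale · g((t − t_init)/dur)     t_init ≤ t ≤ t_sat
R(t) = 1 + scale                           t > t_sat    (plateau)
```

with `g` a rescaled logistic (exactly 0/1 at the window edges, 1/2 at the
midpoint; a piecewise-linear alternative is selectable). The steepness
default is 1.0 — a gentle sigmoid. This matters for onset detection: any
threshold detector fires with latency ≈ (threshold excess)/(early rise
slope), and single-cell caspase activation is switch-like (rises of
minutes, not hours), so the defaults put that latency below one 20-s frame
at the reference noise level. Index definitions do not depend on the shape
choice.

An optional early ratio dip (an emission artifact of the intracellular
environment, not cleavage) is modeled as a subtractive half-cosine bump.
It is off by default and starts only after the 10-frame normalization
window (`dip_delay`, default 240 s), because a dip inside the "initial
values" window would silently redefine the baseline. Its magnitude is a
placeholder; no calibrated value exists for it.

Cell-to-cell heterogeneity is drawn from truncated-normal marginals on the
latent parameter vector (t_init9, dur9, scale9, promotion, completion,
scale3), coupled by a Gaussian copula. Defaults (seconds; truncation at
±3.5 σ plus physical floors):

| parameter  | mean | SD  | meaning                                   |
|------------|------|-----|-------------------------------------------|
| t_init9    | 1200 | 80  | caspase-9 onset after stimulation          |
| dur9       | 240  | 30  | caspase-9 rise duration                    |
| scale9     | 0.6  | 0.1 | caspase-9 net normalized ratio increase    |
| promotion  | 300  | 100 | onset(c3) − onset(c9)                      |
| completion | 420  | 100 | saturation(c3) − saturation(c9)            |
| scale3     | 1.0  | 0.15| caspase-3 net increase                     |

Derived quantities: t_sat9 = t_init9 + dur9, t_init3 = t_init9 +
promotion, t_sat3 = t_sat9 + completion. Cells whose implied caspase-3
rise duration falls below 100 s are redrawn. The recording covers 130
frames (2600 s), ending shortly after the latest possible saturation so
that the time-at-max index is informative rather than a draw from a long
flat plateau.

Two correlations are planted by default: r(scale9, completion) = −0.8 —
the cascade's headline structure, cumulative initiator output inversely
controlling executioner completion time — and r(dur9, completion) = −0.27.
The second value is not free: with integration ≈ scale·dur/2, the delta
method gives r(integration9, completion) ≈ (μ_dur σ_s r_s + μ_s σ_dur
r_d)/sd(scale·dur) = −0.8 exactly when r_d = −0.27, so both the response
scale and its integration carry the −0.8 coupling. The onset and promotion
SDs are sized so that mechanical couplings through shared landmarks
(onset(c9) with onset(c3), saturation with saturation, scale9 with
saturation(c3)) stay below ≈0.65 — the planted pairs, not their shadows,
dominate the cross-probe correlation structure, and initiation/saturation
couplings remain weak, matching the qualitative finding the population is
built to embody. The copula-implied latent correlation matrix is checked
for positive semi-definiteness and infeasible requests are rejected.

Non-responders (optional fraction) are cells whose caspase-3 trace stays
flat; they exercise the exclusion logic.

### Ground-truth records

Every cell carries the index values its noiseless trajectory implies.
Threshold-crossing times are computed analytically from the closed-form
inverse of the rise shape and then snapped to the first qualifying frame,
because the detection rules report frame times; window-bound quantities
(slope, integration, time-at-max) are evaluated on the sampled noiseless
trajectory, since their definitions are grid quantities (least-squares
fit, trapezoid sum, argmax). On noiseless data the full pipeline
reproduces these records exactly; under noise they are the oracle that
recovery rates are measured against.

### Rendering

**Channel traces.** The cleaved fraction f(t) is inverted in closed form
from the ratio trajectory through the probe model: intact probes emit
quenched donor (factor 1−E) plus sensitized acceptor (E), cleaved probes
emit full donor; a direct-excitation term κ keeps acceptor emission (and
the ratio) finite at full cleavage. Defaults E = 0.75/0.70 (caspase-9/-3)
and κ = 0.12 give dynamic ranges of ≈29× and ≈23× — far above the
plateau ratios reached — while keeping the quenched donor bright enough
that channel noise maps to comparable relative noise on the ratio.
Channel intensities are the 4×4 column-normalized mixing matrix applied to
the four emission series, plus zero-mean Gaussian noise proportional to
the local signal — ROI means over many pixels are approximately Gaussian,
which is why no Poisson model is used at the trace level. The default
channel noise (0.5% of signal)
realizes ≈1% noise on the unmixed normalized ratio — the same reference
noise level the direct ratio-trace renderer applies as an absolute SD.
Per-cell probe load is lognormal (CV 0.2); it cancels in normalization.

The default mixing weights are a plausible diagonal-dominant leakage
pattern (condition number ≈1.5), explicitly synthetic: the real emission
spectra are only published graphically, so these weights are placeholders,
not calibration.

**Image stacks.** Cells are uniform disks on a dark background; every
pixel follows the cell's channel trace plus independent pixel noise, and
the label mask carries the cell ids. Because unmixing is linear, ROI
averaging commutes with per-pixel unmixing, so the image path and the
trace path agree exactly on noiseless data (verified, not assumed).

**Bulk (in vitro) mode.** A fixed enzyme dose cleaving a probe pool:
f(t) = 1 − e^{−kt}, ratio = r0 + (r_max − r0)·f. Half of the total change
occurs at ln(2)/k, which the tests check against the sampled curve.

## Index definitions and numerical choices

All indices operate on the normalized ratio (baseline ≡ 1 by division by
the mean of the first 10 frames; the normalized baseline mean is 1 to
1e-12 by construction).

* **Initiation** — candidates are scanned left to right; each candidate
  frame is compared against mean + 3·SD of the 10 frames immediately
  preceding it, and the first candidate beginning a run of 3 consecutive
  frames strictly above its threshold wins. The per-candidate window
  breaks the circularity of defining the baseline by the increase it
  precedes. An SD floor of 1e-4 keeps the rule usable on noise-free
  traces. A useful property of the trailing window: a pure linear trend
  never fires the rule (the window mean lags by 5.5 frames ≈ 0.055·rate
  while 3·SD of the trend is ≈ 0.086·rate), so slow drifts and the dip's
  smooth recovery do not produce false onsets; only convex acceleration
  above a locally flat baseline does.
* **Saturation** — the first 3-frame window at or after initiation whose
  mean reaches baseline + 0.95 × (net maximum), where the net maximum is
  the largest 3-frame window mean. Judging window means rather than single
  frames is what the run-length requirement is for: a single noise spike
  can neither raise the plateau criterion nor break an attained plateau.
  On noiseless traces this coincides with the plain threshold crossing
  (a step trace saturates at the step frame). The result is clipped to
  the time of the global maximum, which is also the fallback.
* **Duration** = saturation − initiation, exactly.
* **Response scale / maximum ratio** — max of the normalized trace minus
  1, and the max itself. Under noise the max carries an upward bias of
  roughly σ√(2 ln n_frames); accuracy statements about the scale are
  therefore medians across cells.
* **Slope** — least-squares line fit on [initiation, saturation] (1/s); a
  degenerate single-frame window falls back to a two-point difference.
* **Integration** — trapezoidal area of max(trace − 1, 0) over
  [initiation, saturation] (s·ratio units), the cumulative-activity
  reading of the rise.
* **Time at max** — time of the global maximum, reported separately from
  saturation; frames within 1e-12 relative of the max count as ties and
  the first is taken, so an exactly flat plateau is insensitive to
  last-ulp perturbations such as a global intensity rescale.
* **Cross-intervals** (signed, c3 landmark minus c9 landmark): promotion =
  initiation₃ − initiation₉; completion = saturation₃ − saturation₉;
  activation = initiation₃ − saturation₉. Defined only when both probes
  responded; the population filter keeps cells with both responses,
  positive durations and scale ≥ 0.05, logging every exclusion with a
  reason code.

Unmixing is ordinary least squares per frame by default (nonnegative
least squares selectable for noisy data); OLS refuses models whose
condition number exceeds 1e6, which the model builder also flags at
construction. Column-sum normalization of the mixing matrix fixes the
abundance scale; the choice is immaterial because all downstream
quantities are ratios or normalized. Whether unmixing precedes or follows
ROI averaging is likewise immaterial under OLS (linearity), and both
orders are supported.

Population statistics: Pearson correlations (Spearman selectable) on all
19 index columns, displayed with R in the lower triangle and R² in the
upper, positive red / negative blue; no multiple-testing correction is
applied to the heatmap (a Benjamini–Hochberg overlay would be an add-on,
deliberately separate). The between-caspase comparison is a paired t-test
by default — both measures come from the same cells — with an unpaired
option. Degenerate guards: identical columns give t = 0, p = 1; a
constant nonzero paired shift gives t = ±∞, p = 0. Zero-variance columns
yield NaN correlations with a warning, never a silent 0.

## What the generator does and does not emulate

It emulates: heterogeneous sigmoidal activation with realistic
single-cell timescales, planted cross-index correlation structure,
spectral cross-talk, signal-proportional Gaussian noise, dim-donor noise
amplification through unmixing, probe-load variation, non-responders, and
an optional early ratio dip.

It does not emulate: photobleaching (none is corrected for, matching the
measurement protocol; a no-op hook exists), cell movement or segmentation
error (masks are inputs), spatial activation gradients within a cell,
focus drift, or mechanistic caspase network dynamics (no ODE model; the
trajectory is phenomenological). Passing tests therefore demonstrate that
the analysis recovers what it claims under these idealized conditions;
they do not certify segmentation quality or bleaching robustness on real
microscope data.

## Problem sizes and determinism

The self-check suite (also run by `scripts/acceptance.py`) uses: 100
random mixing models for the round-trip check; 200 cells at 1% ratio noise
for index recovery and correlation-structure recovery; 100 replicates of
44 cells for the paired-comparison power estimate; 3-cell image stacks at
64×64 for path-consistency checks. These sizes keep the whole suite under
a minute while leaving the sampling error of each reported rate well
inside its margin. Every random draw descends from a single seed;
identical seed and configuration reproduce identical outputs, and the
pipeline writes a manifest (resolved config, config hash, seed, versions)
before executing.

## Known limitations

* The mixing weights and probe photophysics are plausible placeholders,
  not spectral calibration; analyses of real data must supply a measured
  mixing matrix (JSON).
* The onset rule inherits the latency of any threshold detector; for
  rises much slower than the defaults (duration/scale ≳ 1200 s per ratio
  unit) detected onsets lag the true onset by more than the rule's noise
  floor suggests.
* The scale estimator (trace maximum) is noise-biased upward; prefer the
  integration index when comparing cumulative activity across noise
  levels.
* Cross-interval sign conventions are a choice (documented above and
  configurable); the field uses several.
* The five qualitative single-cell response patterns sometimes seen in
  this kind of data are out of scope; no classifier is provided.
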