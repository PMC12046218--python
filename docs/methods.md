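# Methods

`loomphot` analyzes fiber-photometry and behavioral data from the looming
stimulus assay: a mouse explores a 61 × 20.3 cm arena with a shelter at one
end; after a 5-min exploration period, entry into the 20 × 20 cm threat zone
at the opposite end triggers a train of five expanding overhead disks, which
drives escape to the shelter. Dopamine release is monitored with a
genetically encoded sensor (dLight1) through a two-channel photometry system
(465 nm signal, 405 nm isosbestic reference). The package implements the
full analysis chain plus a ground-truth synthetic-session generator, so that
every stage is testable without recorded animal data.

## Photometry model and preprocessing

Each channel is modeled as

    F_465(t) = B_465 + A_465 e^(−t/τ_b) + a(t) + Σ_i c_i k(t − t_i) + ε_465(t)
    F_405(t) = B_405 + A_405 e^(−t/τ_b) + a(t) + ε_405(t)

where `a(t)` is a shared motion artifact (Ornstein–Uhlenbeck, SD 1 a.u.,
τ 0.5 s), the exponentials are photobleaching, `k` is the transient kernel
(difference of exponentials, rise 0.1 s, decay 0.8 s, unit peak; time to
peak ≈ 0.24 s), and `ε` is per-channel white detector noise (SD 0.2 a.u.).
Transients — evoked, escape-associated, and spontaneous — appear only in the
465 nm channel.

Preprocessing:

1. **Band-limit** both raw channels with a 2nd-order zero-phase Butterworth
   low-pass, default 1.5 Hz. The cutoff matches the sensor's information
   band (≈100 ms off-kinetics; kernel FWHM ≈ 0.7 s), acts as an approximate
   matched filter for transient amplitude estimation, and — because it is
   applied *before* the correction fit — prevents per-channel detector noise
   from attenuating the reference slope (errors-in-variables) and leaking
   shared artifact into ΔF. Filtering is linear, so it commutes with the
   subtraction itself.
2. **Isosbestic correction**: a first-order polynomial (straight line) is
   fitted by ordinary least squares to predict the 465 nm signal from the
   405 nm reference over the whole recording, and the fitted model is
   subtracted: ΔF = F465 − (a·F405 + b). ΔF is kept unnormalized (no
   division by F₀); z-scoring removes scale. Fitting the reference onto the
   signal (rather than rescaling the signal) leaves transient shapes
   untouched. The whole-recording fit is a configurable choice; it is
   recorded with the outputs.
3. **Epoch z-scoring**: ΔF is z-scored using the mean and sample SD
   (n − 1) of a baseline epoch — by default the 240 s of pre-trigger
   exploration ending 1 s before the trigger. A long epoch keeps the SD
   estimate stable (the multiplicative error of a T-second epoch scales as
   1/√T); the 1-s gap keeps the acausal pre-ring of the zero-phase filter
   from leaking evoked signal into the normalization window. A symmetric
   epoch around the trigger is available through `z_epoch_post`.

## Transient statistics

Peaks are local maxima with prominence ≥ 0.5 z and separation ≥ 0.25 s
(plateau ties break to the earliest sample). The **per-window response
amplitude** (per disk, at escape onset, at movement onset, and for the 1-s
prestimulus baseline) is the largest qualifying peak in the window; when no
local maximum qualifies, or when the window's maximum sample (typically at
a boundary) exceeds every interior peak, the window maximum is used and
flagged. The boundary rule matters in practice: with onset jitter near the
end of its range plus filter broadening, a transient can culminate at the
very edge of the 1-s response window, and reporting a smaller interior noise
bump instead would be clearly wrong. The prestimulus baseline statistic
deliberately mirrors the response statistic so that their null distributions
coincide; on default synthetic sessions it averages ≈ 1.0–1.2 z, i.e. it
approximates the amplitude of spontaneous release events and noise, as in
the real assay.

Event-aligned matrices use nearest-sample indexing (no interpolation; grid
error ≤ half a sample) and drop events without full pre/post coverage
rather than padding, which would bias the SEM.

Because the transient kernel decays with τ = 0.8 s while consecutive disks
are 1.0 s apart, the disk-2 response window partially contains the disk-1
tail; with the default kernel, stimulus-number habituation therefore shows
most clearly from disk 3 onward.

## Behavior

Positions are smoothed with a 0.2 s centered moving average before centered
finite differencing (one-sided at the endpoints); speed is the velocity
magnitude and acceleration the derivative of speed. The trigger is the
first in-threat-zone sample at or after the exploration period (default
300 s). An escape bout starts at the first post-stimulus time with speed
≥ 10 cm/s sustained ≥ 0.2 s and requires shelter entry (centroid crossing,
no dwell requirement) within 10 s of disk-1 onset; latency is measured from
disk-1 onset to movement onset. Peak velocity and acceleration are taken
between onset and shelter entry. Movement bouts are maximal intervals with
speed ≥ 2 cm/s, merged across gaps < 0.5 s, that reach ≥ 20 cm/s; freezing
is speed < 1 cm/s sustained ≥ 1 s outside the shelter. None of these
thresholds are prescribed by the assay itself; all live in
`AnalysisConfig`. A mouse is an escaper iff its threat trial produced an
escape bout; the escaper/non-escaper shelter deadline (10 s) is likewise a
package choice.

## Synthetic sessions

The behavioral script is: reflected-OU exploration (velocity SD 8 cm/s,
τ 1 s) with one scripted vigorous movement bout (raised-cosine to 30 cm/s);
a walk to the threat-zone edge that decelerates to 5 cm/s before crossing
(so the crossing itself cannot trip the escape-onset detector); a
stimulus-arrest dwell of slow orienting movement (OU, 2 cm/s — a pause in
locomotion, not immobility, so it is not classified as freezing); then, for
escapers, a raised-cosine speed ramp whose peak velocity and peak
acceleration are programmed (ramp time t₁ = π·v_peak/(2·a_peak)), a plateau
to the shelter, and settling inside it. Non-escapers wander on without ever
entering the shelter. Reflections are implemented by folding the integrated
path into the allowed box, which preserves speed exactly.

The evoked transient is injected 0.3–0.6 s (uniform) after disk-1 onset, so
that the simulated peak latency brackets the sub-second evoked peak
latencies of the sensor; an escape-associated transient (mean 2 z,
uncorrelated with the stimulus transient) is injected 0.2 s after escape
onset. Amplitudes are expressed in *nominal z units*: a.u. per z is the
predicted baseline-epoch SD, combining the band-limited white-noise residual
with the variance load of spontaneous events (solved self-consistently in
`z_unit_scale`).

The amplitude–kinematics coupling is linear with Gaussian residuals.
Defaults program population means matching the assay's reported escape
kinematics (latency 3.8 s, peak velocity 56 cm/s, acceleration 360 cm/s²
at the mean amplitude of 3 z) and population R² of 0.80/0.71/0.73 for
latency/velocity/acceleration (`residual_sd_for_r_squared` converts a
target R² into a residual SD). The across-mouse amplitude SD (1.5 z) is
derived from the assay's reported SEMs. Programmed latencies are clipped
below at 1.25 s (flagged): the stimulus-evoked and escape-associated
transients are temporally separate events in the assay, and shorter
latencies would merge them into a single ramp. The inter-mouse SEMs of the
kinematic metrics are reproduced approximately, not exactly.

### What the generator does not emulate

Photon/shot-noise physics, wavelength-dependent artifact gain (the artifact
enters both channels with unit gain, so the correction's ceiling is higher
than in real recordings), hemodynamic contamination, pose and orientation
(the trajectory is a centroid), trial-to-trial within-mouse variability
(one threat trial per session), and video rendering. Passing tests
therefore demonstrate correctness of the analysis chain under the stated
generative model, not robustness to every artifact of real recordings.

## Known limits of amplitude recovery

The z unit is *defined* by the baseline-epoch SD, so the noise floor of the
largest-peak-in-1-s statistic is ≈ 1.4 z (the expected maximum of a few
independent unit-SD draws per window) and its per-session measurement error
is ≳ 0.6–0.9 z for any stationary residual — fast noise contributes an
order-statistic error, slow variance contributes a local-offset error, and
this holds across band-limits (1–5 Hz) and epoch lengths (10–240 s). With
the assay-scale across-mouse amplitude SD of 1.5 z, the injected-vs-
recovered amplitude correlation is therefore bounded near r ≈ 0.85, and an
11-mouse cohort's estimated amplitude–latency R² scatters widely around its
programmed value (sampling noise alone gives the sample R² of 11 points a
90% range of roughly ±0.3 at R² = 0.8). The validation experiments report
these quantities as measured; `coupling_recovery_experiment` additionally
reports the measurement-free "realized" R² coverage to separate sampling
noise from measurement noise. Latency and peak-velocity recovery are
essentially exact (≤ 0.07 s / < 0.1%). Peak *acceleration* is
systematically attenuated (~35%) by the 0.2-s position smoothing at 30 Hz
tracking, because the acceleration pulse of the escape ramp is only
~0.1–0.2 s wide; the smoothing window is configurable when acceleration
fidelity matters more than jitter suppression.

## Statistics

Pearson correlation (two-sided p via the t transform, n − 2 df), paired t
(n − 1 df) and pooled-variance unpaired t (n₁ + n₂ − 2 df), one- and
two-way repeated-measures ANOVA with sphericity-assumed df, Bonferroni
pairwise comparisons (multiplier = number of comparisons actually
performed, capped at 1), and the uncorrected Pearson χ² on 2×2 escape-count
tables (with Yates' correction the printed escape-count statistic would not
be reproduced). Engines are scipy.stats and pingouin; a fully degenerate
repeated-measures matrix (every subject constant across conditions) is
reported as F = 0, p = 1, while a singular error term with a nonzero effect
raises an error.

## Problem sizes used in validation

Recovery experiments use 50 independent sessions at the full default
session length (5-min exploration, 3-min post-trigger recording, 100 Hz
photometry, 30 Hz tracking); coupling recovery uses 100 cohorts of 11
escapers; null calibrations use 2,000 replicates (the disk-response null on
30-s single-trial recordings of 16 mice each). The whole validation suite
regenerates every session from scratch at run time.
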