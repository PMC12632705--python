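# Methods

This note documents the models, defaults and numerical choices behind
`fetodoppler`, and what the synthetic data do and do not establish.

## Synthetic umbilical-artery waveform

One beat of the velocity waveform v(t) (cm/s) is built from two smooth
segments on an integer sample grid:

- systolic upstroke (fraction `systolic_fraction`, default 0.3, of the
  cycle): `sin²` rise from the previous end-diastolic velocity to PSV,
  with zero slope at the peak;
- diastolic decay: `(exp(−k·u²) − exp(−k)) / (1 − exp(−k))` with
  u ∈ [0, 1] and `decay_rate` k = 2.5, falling from PSV to the beat's
  EDV *exactly at the beat's last sample*.

Placing end-diastole at the end of the cycle matters: it makes per-beat
EDV attribution unambiguous (the trough between two systolic peaks
belongs to the earlier beat) and lets absent-EDV beats coexist with
normal neighbors without contaminating their troughs. Each beat spans
`round(sample_rate·60/FHR)` samples, so the per-beat maximum and
end-diastolic sample equal PSV and EDV exactly by construction; the
realized (grid-quantized) FHR is recorded as ground truth. Defaults
(PSV 52.2 cm/s, EDV 20 cm/s, FHR 140 bpm, 200 Hz, 10 s) describe a
healthy third-trimester umbilical artery whose S/D 2.61 / RI 0.62 /
mean FHR ≈ 140 bpm sit at the middle of published reference ranges.
Absent-EDV beats are a seeded draw of exactly
`round(absent_edv_fraction · n_beats)` beats with the diastolic endpoint
forced to 0 (or −0.5·EDV with `reversed_edv`), emulating placental
insufficiency.

## Duplex scene simulator

Scenes are rendered directly in the reconstructed image domain
(beamforming, plane-wave compounding and aberration correction are
upstream hardware/backend concerns and out of scope). A frame pair is:

- **B-mode**: gamma-distributed speckle (mean 120, variance 400 display
  units) with vessel lumina attenuated to 0.2×;
- **color Doppler**: artery pixels carry the instantaneous waveform
  velocity, vein pixels a constant −10 cm/s counter-flow, background is
  zero-mean Gaussian noise (default SD 2 cm/s); all in cm/s with flow
  toward the transducer positive.

Geometry defaults: 50 × 70 mm field, 0.5 mm pixel pitch, 20 frames/s
(the acquisition frame rate is a free parameter of the simulator; 20
frames/s gives the 10-frame default tracking window a 0.5-s span, at
least one cardiac cycle at FHR ≥ 120 bpm), artery radius 3 mm, vein
radius 4 mm at a fixed 11 mm offset. Trajectories: static, linear,
sinusoid, or a smooth random walk (AR(1)-filtered velocity capped at
`max_speed`, default 2 mm/s) of the vessel *pair*. Coordinates are
stated in every output: lateral = mm from the left field edge, axial =
depth in mm, pixel centers, 0-based. One integer seed threads every
stochastic draw; identical seed + spec is bit-identical.

What the simulator does **not** emulate: anatomical context (cord
curvature, fetal structures), maternal tissue layers, depth-dependent
attenuation or focusing, speckle decorrelation with motion, wall
filters, or out-of-plane motion. Tracking and recovery results on these
scenes therefore demonstrate algorithmic correctness under the stated
motion/noise model, not clinical performance.

## Spectrogram synthesis and the circular velocity axis

The pulsed-Doppler Nyquist velocity is
v_nyq = (PRF/2)·c / (2·f₀·cosθ); at the default PRF 3000 Hz, carrier
2.5 MHz, θ = 0 and c = 1540 m/s, v_nyq = 46.2 cm/s. Velocities map onto
a circular axis modulo 2·v_nyq (aliasing): each time column holds a
Gaussian ridge centered at the wrapped velocity with
σ = max(`broadening_sd`, bin/2) — the floor gives a "noise-free" ridge a
finite one-bin spectral width — normalized to unit column power, plus
i.i.d. exponential noise with per-bin mean `noise_floor` (0 = off).
256 velocity bins by default (0.36 cm/s at the default Nyquist span).

## Envelope extraction

Per time column: (1) subtract a noise floor (default estimate: 3× the
median power of the spectrogram, ≈ 2.1× the mean of an exponential
background and exactly 0 for noise-free input; the estimate scales with
the data, making the envelope invariant to uniform power scaling);
(2) establish the flow direction from the sign carrying the majority of
above-floor power; (3) walk the velocity axis outward from zero along
that direction, continuing circularly past ±v_nyq so aliased flow is
unwrapped; (4) stop at the bin where cumulative above-floor power
reaches `power_fraction` (default 0.95) of the column total; (5) refine
to sub-bin precision with a power-weighted centroid over ±3 bins around
the crossing. The refinement removes both the bin-grid quantization and
the ≈ 1.6σ upward bias an edge-percentile estimator has under symmetric
ridge broadening; without it, per-beat indices inherit a velocity-scale
bias larger than the rounding resolution of published index values.
Unwrapped velocities beyond `alias_limit` (1.5 × v_nyq) are
reinterpreted as counter-flow — a baseline cut of the circular axis, so
mild reverse flow is not mistaken for extreme forward aliasing. A
constant supra-Nyquist flow is inherently ambiguous and is reported on
the majority side. Columns with no above-floor power are flagged and set
to zero. Optional moving-median smoothing (`smooth_window`, default 1 =
off) is available for dropout-ridden records.

## Beat detection and per-beat hemodynamics

Systolic peaks are picked (scipy `find_peaks`) on a median-3-smoothed
copy of the envelope with minimum separation 60/FHR_max and prominence
0.3× the envelope range; amplitudes are then measured on the
*unsmoothed* envelope within ±3 samples of each detected landmark.
Detect-on-smoothed / measure-on-raw keeps robustness to single-column
outliers without the median filter clipping single-sample systolic
peaks or end-diastolic troughs (which would bias RI low by more than
its reporting precision). A beat runs peak-to-peak: PSV = local maximum
at the peak, EDV = trough immediately before the next upstroke (the
minimum of the smoothed envelope over the second half of the cycle,
measured on raw; robust to dicrotic notches), TAV = cycle mean,
FHR = 60/interval. Beats outside the physiological band (60–240 bpm
default) are rejected. Absent EDV is declared at ≤ 2 cm/s, reversed at
< −2 cm/s; S/D is reported as NaN for absent-EDV beats and excluded
from segment means (RI stays defined: 1 at absent, > 1 at reversed, and
is retained) — this is why a severely compromised recording can show a
mean S/D and mean RI that look mutually inconsistent under the
textbook identity RI = 1 − 1/(S/D), which holds only beat-wise with
EDV > 0.

## Vessel tracking

The pulsatility map is the per-pixel population variance of |color
velocity| over a sliding window (default 10 frames; magnitude so that
aliased sign flips do not masquerade as pulsatility). Before
thresholding, the map is smoothed with a 3×3 box filter
(`presmooth_px = 1`): pixels at a moving vessel's *edge* toggle between
flow and background and carry several times the interior variance, so
an unsmoothed fraction-of-max threshold locks onto edge slivers and
fragments the vessel. Threshold policy: fraction-of-max (default 0.3;
Otsu available), 8-connected components, regions under 20 px dropped.
The primary region is the largest by area (ties: higher mean variance,
then shallower centroid — ties essentially never occur on real maps);
the gate is its unweighted pixel centroid. On loss (no supra-threshold
region) the last valid gate is held and the step flagged `lost`;
tracking resumes on reacquisition. The gate is reported at the window's
last frame — causally correct for a real-time system — so the estimate
reflects the window-average position and trails fast motion by about
half a window; accuracy checks against ground truth at the same frame
remain well inside the 2-mm clinical criterion at the simulated motion
speeds.

## Monitoring analytics

Records are segmented into consecutive fixed intervals (default 600 s)
from the first beat; the incomplete trailing interval is dropped (a
~70-min session yields 7 segments). FHR variability is the
within-segment sample SD (ddof = 1) of per-beat FHR — the variability
metric is not standardized, so alternatives can be derived from the
per-beat tables. Stratified box statistics use numpy's linear
interpolation percentile rule (stated in output metadata; conventions
differ across ecosystems). FHR accelerations follow the
cardiotocography convention: ≥ 15 bpm above a centered rolling-median
baseline (120 s) sustained ≥ 15 s. FHR-vs-index association uses
Spearman rank correlation with a seeded permutation p-value.

## Agreement statistics

Bland–Altman: differences a − b, sample SD (n − 1), limits of agreement
mean ± 1.96 SD. Repeated measures per participant are pooled without
within-subject correction (matching how such plots are commonly drawn);
per-subject averaging can be applied upstream. Gate discrepancy is
per-axis |Δ| with within-threshold fractions (2 mm default); the
Euclidean fraction is also reported since a per-axis criterion is the
looser of the two.

## QA and acoustic-output calculators

Pixel spacing Δ = extent/(N − 1) per axis. FWHM uses sub-sample linear
interpolation at the half-maximum crossings with background taken as
the median of the outer 10% tails on each side; a plateau of equal
maxima is accepted (top-hat), disjoint equal maxima are rejected as
ambiguous. CNR = (μin − μout)/√(σin² + σout²) on displayed
(log-compressed) intensities. Dynamic range fits grey value against
nominal contrast (grey-on-contrast, matching "contrasts corresponding to
grey values 255 and 0") and reports 255/slope. Hydrophone sensitivity:
V/Pa = 10^((dB re 1 V/µPa + 120)/20); loaded sensitivity
ML = G·MC·CH/(CH + CA + CC) (defaults G 20 dB, CH 70 pF, CA 7 pF,
CC 1.6 pF). Intensity metrics from a single-pulse pressure waveform:
i = p²/(ρc) with ρ = 1000 kg/m³, c = 1540 m/s defaults; the pulse
window is the central 90% of the pulse intensity integral, Isppa its
mean intensity, Ispta = PII·PRF, peak rarefactional pressure = −min p.
Derating uses the 0.3 dB/(cm·MHz) soft-tissue convention (pressure
10^(−A/20), intensity 10^(−A/10)); MI = derated p_r [MPa]/√(f [MHz]).
Plane-scan power integrates intensity × pixel area over the beam
cross-section where intensity ≥ −26.2 dB of peak. Thermal indices are
not computed (standards-defined measurement procedures, not printed
formulas); the acoustic power that feeds them is.

## Problem sizes and verification scope

The bundled verification (`scripts/acceptance.py`, `tests/`) uses 10-s
waveforms at 200 Hz, 256-bin spectrograms, and ten 100-frame scenes at
20 frames/s — sizes chosen so the full chain (including an 18-cell
FHR × S/D × SNR parameter-recovery grid) verifies in seconds while
exercising every code path, including supra-Nyquist aliasing and
absent-EDV accounting. Tests assert recovery of generator ground truth
(S/D within 10%, RI within 0.05, FHR within 2 bpm under noise; exact
identities where construction forces them), equivalence with
independently coded oracles (two-pass variance, trapezoidal TAV,
closed-form truncated-Gaussian beam power, two-line Bland–Altman), and
invariances (translation equivariance of the gate, scale invariance of
the envelope, seed reproducibility to the byte).

## Known limitations

- The envelope tracks a single spectral ridge (plug flow); full
  velocity-distribution spectra (parabolic profiles, spectral window
  effects) are not modeled.
- Tracking and spectral acquisition are sequential in the emulated
  system; the tracker holds the gate during loss rather than predicting
  motion.
- Absent-EDV detection thresholds on envelope velocity; very low but
  present diastolic flow below 2 cm/s is classified absent.
- The monitoring module treats beats as equally weighted within a
  segment (no duration weighting).
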