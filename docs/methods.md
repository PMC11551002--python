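# Methods

## The analysis problem

A TMS pulse over the motor cortex hand area (M1) evokes a motor-evoked
potential (MEP) in contralateral hand muscles, measured with surface EMG.
MEP amplitude falls off with coil distance from the optimal scalp site
(the hotspot) and with coil orientation away from the preferred
induced-current direction, and depends strongly on motor state: during
natural dynamic movement the recruitment threshold is far below the
resting motor threshold, so effective stimulation reaches much further
across the scalp. The package quantifies these effects from epoched EMG:
event-related average MEPs per condition cell, orientation-preference
circular statistics, interpolated scalp *t*-maps with thresholded contour
areas, recruitment curves with threshold rules, proximity screening, and
links to externally modeled electric fields.

## Preprocessing

Continuous EMG (mV, 1–20 kHz) is band-pass filtered at 25–250 Hz with a
second-order Butterworth run forward and backward (zero phase, effective
order four) so MEP onset latencies are not delayed. Epochs span −200 to
+200 ms around each trigger, the sample nearest the trigger at t = 0
(ties resolved toward the earlier sample); triggers too close to a record
edge are dropped with a logged count. Averaging epochs within a condition
cell suppresses background EMG by √n while leaving the pulse-locked MEP,
which is essential when stimulating during ongoing movement.

MEP amplitude is the peak-to-peak of the averaged trace in the 10–50 ms
window; the −50 to −10 ms window provides a matched pre-TMS control with
the same number of samples. Amplitudes are normalised by the maximum
post-TMS amplitude per participant and muscle (optionally per task, a
more stringent scope that removes overall state differences before
orientation comparisons); pre-TMS amplitudes are divided by the same
factor so the post−pre contrast stays on one scale.

## Automatic onset latency

The onset detector reports the earliest time in (10, 50) ms at which the
trace departs from the baseline (−200 to −50 ms) mean by more than a
threshold, sustained for 2 ms. The threshold is the larger of 3 baseline
SDs and 25% of the maximum deviation in the search window. The relative
floor is deliberate: zero-phase filtering of a biphasic MEP produces an
acausal precursor reaching ≈20% of the peak several milliseconds before
the true onset, and a purely noise-referenced detector locks onto that
ripple for large MEPs, producing amplitude-dependent spuriously early
onsets. The floor adds a small constant delay (the rise to 25% of peak,
≈0.3 ms for a ~120 Hz biphasic wave) that is common to all conditions and
cancels in comparisons. All three parameters are exposed.

## Threshold rules and detection evidence

Thresholds are evaluated offline over a supplied intensity ladder (5 %MSO
steps). The resting rule takes the lowest intensity with ≥5 of the last
10 trials above criterion; the active rule additionally accepts the
averaged-trace amplitude exceeding the criterion. The rule functions are
pure and operate on caller-supplied per-trial evidence. The pipeline
supplies the *post-minus-pre peak-to-peak contrast* with a noise-guarded
criterion, `max(50 µV, 1.96 × SD of the pre-window peak-to-peak across
trials)`: during movement the raw post-window peak-to-peak saturates on
background EMG alone (a single dynamic-task trial's background
peak-to-peak is ~0.4 mV), so a raw 50 µV rule would be meaningless there.
The guarded contrast automates the experimenter's "is an MEP visible on
this trial?" judgment; in quiet recordings it reduces to the plain 50 µV
criterion.

Recruitment curves report group means, 95% CIs and contributing n per
intensity (MEPs are not detectable in every participant at every
intensity). The first significant intensity requires both a one-sample
*t* on the post−pre contrast rejecting zero (two-tailed α = .05,
uncorrected across intensities) *and* a detected MEP in more than half of
the contributing participants. The detection gate matters: with seven
intensities tested independently, a *t*-only rule has a ~30% family
false-positive rate at a genuinely silent site, which would defeat the
qualitative "no response at any intensity at rest" contrast the curve
exists to establish.

Latency comparison at matched amplitudes ranks all intensity pairs across
two curves by |group mean amplitude difference| (candidates restricted to
intensities with latencies in ≥10 participants) and runs paired *t* tests
on amplitudes (match check) and latencies (the question). Under a single
neural source, matched amplitude implies matched effective drive and
hence matched latency.

## Maps

Per-location *t* statistics are paired *t* across participants on the
post−pre normalised amplitude contrast. Maps interpolate *t* linearly on
a Delaunay triangulation — exact at the nodes, no overshoot, so no
spurious significant islands — evaluated on a 1 mm grid clipped to the
convex hull (no extrapolation). The significant area integrates
{t > t_crit} with marching-squares sub-cell polygons (default t_crit =
2.20, two-tailed α = .05 at df = 11, overridable). Because the published
mapping literature does not fix an interpolant, absolute areas are
interpolation-dependent; the package treats area orderings (e.g. dynamic
vs rest) as the meaningful output. No correction for multiple comparisons
is applied across locations: neighbouring sites are strongly
autocorrelated, and significance claims rest on hypothesis-driven site
tests, not the map.

## Spatial linking

Proximity screening flags targets within 55 mm of the M1 hotspot on the
scalp or 42 mm in MNI space — the empirical reach of movement-state
stimulation. The E-field sweep correlates externally modeled field
magnitudes with MEP amplitudes while excluding points below a field
threshold (0–79 V/m, 1 V/m steps; ≥3 points required), reporting the
smallest threshold attaining the maximum correlation; both the
per-table best threshold and means across tables can be aggregated. IDW
volumes weight site MEPs by normalised inverse distance (exponent 1,
weights summing to 1 per voxel, so values are convex combinations and
independent of grid extent), threshold at the volume mean, and rescale
survivors by the maximum — dividing by the max rather than min–max so
thresholded-out voxels remain distinguishable from the weakest survivors.

## Statistics and power

Within-participant effects use one-sample *t* on contrasts with Cohen's
d_z = mean/SD. Effects combine by fixed-effect inverse-variance weighting
with Var(d) ≈ 1/n + d²/(2n) (an unweighted mean is selectable; the exact
weighting behind published combined effects is rarely stated, so the
choice is a labelled knob). Sample size defaults to the normal
approximation, minimum 2; the noncentral-*t* exact option is more
conservative (never smaller).

## The synthetic-experiment generator

No generative model exists for these data, so the generator uses the
simplest mechanism reproducing the four qualitative phenomena the
analysis must detect — distance decay, orientation tuning,
state-dependent thresholds, latency–intensity coupling:

    drive  = intensity · exp(−‖coil − hotspot‖² / 2σ²) · exp(κ(cos(θ−θ₀)−1))
    amp    = A_max · sigmoid((drive − T_task)/s) · LogNormal(0, σ_trial)
    lat    = lat_max − (lat_max − lat_min) · sigmoid((drive − T_task)/s) + jitter
    T_task = RMT for rest/isotonic, 0.61·RMT for dynamic movement

Intensity and `rmt_drive` share a %MSO-like scale (drive = intensity at
the hotspot with the preferred orientation). Defaults, with rationale:

| parameter | default | unit | why |
|---|---|---|---|
| `rmt_drive` | 55 | %MSO | typical resting thresholds (≈52–64 %MSO across cohorts) |
| `active_threshold_ratio` | 0.61 | – | dynamic-movement thresholds average ~61 %RMT |
| `sigma_space` | 42 | mm | jointly satisfies: a site 55 mm away is recruitable during movement near ~110 %RMT yet silent at rest up to ~1.6×RMT |
| `slope` | 2 | %MSO | puts the 50 µV crossing within one 5 %MSO ladder step below `rmt_drive`, as a threshold rule presumes |
| `kappa_orient` | 2 | – | strong North-East preference (45°), near-null at the opposite orientation |
| `amp_max_mV` | 2 | mV | grand-average MEPs of 1–10 mV at the single-trial level |
| `latency_min/max_ms` | 21.5 / 25.5 | ms | hand-muscle MEP onset range across intensity |
| `latency_jitter_ms`, participant offset | 1.0 / 1.0 | ms | within/between-participant latency SDs of ~1–2 ms |
| `background_rms_mV` | .005/.05/.1 | mV | rest / isotonic / dynamic background EMG |
| `burst_mod` | 0.8 | – | 0.5–3 Hz amplitude modulation mimicking movement bursts |
| `trial_noise_sigma` | 0.5 | – | log-normal trial-to-trial MEP variability |
| hotspot / RMT jitter | 7 mm / 5 %MSO | | between-participant anatomical and threshold spread |

Background EMG is white noise shaped to 10–500 Hz (emulating online
acquisition filtering) and scaled analytically to the task RMS; dynamic
background is additionally amplitude-modulated so averaging-based
background suppression is exercised against non-stationary noise. The MEP
waveform is a damped sinusoid (~120 Hz, ~12 ms); only its peak-to-peak
amplitude and onset are contractually meaningful. One RNG stream per
dataset is split per participant by seed offset, so any participant's
data are reproducible in isolation.

What the generator does *not* emulate: real MEP waveform shapes and their
muscle dependence, stimulation artifacts, coil drift and heating breaks,
fatigue and habituation, correlated background across muscles, and any
biophysics of field propagation (the Gaussian distance decay is a scalp-
level abstraction, not a head model). Passing recovery tests therefore
demonstrate that the *analysis* is correct and well calibrated under the
assumed statistical structure, not that the model captures every property
of real recordings.

## Simulation studies and problem sizes

The end-to-end studies (`mepmap.studies`) run 12 simulated participants —
the canonical group size for this within-participant design — with 10–20
trials per cell, at a 2 kHz sampling rate (within the standard 2–10 kHz
EMG acquisition range; the generator's default remains 5 kHz). Recovery
rates are evaluated over 20 seeded replicates in the test suite and 10 in
the acceptance script. Choices worth noting:

* hotspot hunting stimulates at 100 %RMT, where the recruitment sigmoid
  is steepest and spatial contrast between neighbouring grid nodes is
  maximal, as in clinical hotspot searches near threshold;
* the 27-site map fixture is an idealised concentric arrangement
  (centre + rings of 8, 8, 10 sites at 25/50/75 mm); published
  per-participant site tables are approximated, not reproduced;
* the distant-site analogue sits 39 mm lateral and 39 mm posterior to the
  hotspot (≈55 mm), matching the supramarginal-gyrus geometry.

## Numerical notes

* Marching-squares cell areas are exact for the linear edge model; the
  saddle ambiguity is resolved by the boundary-walk orientation. NaN
  (outside-hull) corners count as below threshold, slightly
  under-measuring areas that touch the hull boundary.
* The resultant vector is reported directionless when its length is
  numerically zero (≤1e−12 relative to the amplitude scale).
* Compass labelling assigns the nearest of 8 points with ties going to
  the counterclockwise-higher angle (112.5° → NW).
* Degenerate inputs are signalled errors where a statistic is undefined
  (zero-variance contrasts, all-zero normalisation groups, collinear
  layouts) and values where absence is informative (no latency detected,
  no threshold reached, no significant intensity).
* CSV floats are written with 17 significant digits and parsed with
  correctly-rounded conversion, so on-disk round-trips are exact.

## Known limitations

Absolute map areas depend on the interpolant and site geometry; only
within-pipeline comparisons are meaningful. The latency detector's
relative floor biases onsets slightly late (and the acausal filter
precursor slightly early); both effects are condition-invariant and
cancel in contrasts, but absolute latencies should be read with ~0.5 ms
caution. The E-field sweep consumes modeled field tables as given; no
field computation, head meshing, gray-matter masking, MNI warping or
volume smoothing is performed.
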