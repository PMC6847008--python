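# Methods

This note documents the models behind `gqkinetics`, the defaults and why
they were chosen, the numerical decisions, and what the synthetic-data
tests do and do not establish about real data.

## Event-kinetics assay

### FRET efficiency and the observation window

Traces are analysed as the raw proximity ratio `E = I_A / (I_D + I_A)`
without gamma-factor or leakage corrections: the dual thresholds were
defined on uncorrected traces, and the donor-leakage population (E ≈ 0.12)
is modelled as a histogram component rather than subtracted. Negative
(over-subtracted) intensities are clamped to zero before the ratio; frames
with non-positive total intensity are undefined and skipped everywhere.

Each molecule's usable window runs from the first frame to photobleaching
or the end of the movie, whichever comes first. Two detectors bound it:

* **Donor bleach** — the trailing running median (window 5 frames) of the
  total intensity drops below 0.5× its initial value. The median makes the
  detector robust to single-frame noise; the drop fraction of 0.5 separates
  "both dyes dark" from ordinary intensity fluctuations at the simulated
  noise levels.
* **Acceptor bleach** — the efficiency collapses permanently to the
  donor-leakage level: the earliest frame from which ≥ 90% of the running
  medians stay below `acceptor_efret_cut = 0.2` through the donor-bounded
  end of the trace (for at least a window's worth of frames). The
  permanence requirement distinguishes bleaching from genuine unfolded
  dwells (E ≈ 0.30, which refold); the 90% tolerance keeps rare noise
  excursions from hiding a bleach. The cut of 0.2 sits between the leakage
  level (0.12) and the unfolded level (0.30).

These detector parameters were chosen against simulator ground truth (on
simulated movies the detected window end lands within a few frames of the
true bleach time) and are exposed in the API. A convenient side effect of
the acceptor rule is that donor-only molecules — constant E ≈ 0.12 — get an
empty window and drop out of the kinetics, mirroring the manual practice of
discarding donor-only traces. Molecules with windows shorter than
`min_observation_frames` (default: the detector window) are excluded and
reported; note that very short windows, when admitted, produce heavy-tailed
per-molecule rates (one event over a second is a rate of 1 /s) and inflate
the bootstrap spread.

### Dual-threshold event counting

The counter is a three-state hysteresis machine (DISARMED → ARMED on
`E ≥ 0.55`; ARMED → UNFOLDED on `E ≤ 0.45` held for `min_dwell_frames`
consecutive frames; UNFOLDED → ARMED on `E ≥ 0.55`). Choices:

* `min_dwell_frames = 2` operationalizes the conservative exclusion of
  single-frame dips, which cannot be distinguished from noise. No other
  smoothing is applied — thresholds act on raw per-frame efficiencies.
* Frames strictly between the thresholds never change state, so band
  wander is never double-counted; a dwell run is broken by a between-band
  or high frame but continues across undefined frames (which are treated
  as excised from the series).
* `count_mode="at_dip"` (default) scores the event when the dip is
  confirmed, so an event truncated by photobleaching before refolding still
  counts; `full_cycle` requires the subsequent rise and reproduces the
  strict dip-then-rise signature. Both are implemented because published
  practice is ambiguous on bleach-truncated events; `at_dip` matches the
  worked example in which three events are counted in a window that ends at
  acceptor bleaching.
* Raising the low threshold can only add qualifying dip frames within
  fixed arming boundaries, so the event count is monotone in it — this is
  asserted as a property test, and the whole counter is checked against an
  independent regex-based enumeration over *all* three-symbol traces up to
  length 12, for both modes and dwell 1–3.

### Rates, bootstrap, normalization

The condition-level estimator is the pooled rate Σ events / Σ observation
time (equivalently the time-weighted mean of per-molecule rates); the
unweighted mean of per-molecule rates is reported alongside because the
bootstrap resamples molecules, not time. One published condition table row
(547 events / 10 074 s) prints as 0.055 /s although the quotient rounds to
0.054; the package reports the computed value and the tests document the
discrepancy.

Bootstrap: 20 000 sets, each resampling N per-molecule rates with
replacement and storing the mean. The reported uncertainty is the SD of a
least-squares Gaussian fitted to the Freedman–Diaconis histogram of those
means; the empirical SD and the 2.5–97.5% percentiles are kept as well.
Degenerate cases: if all rates are identical the SD is 0 and no fit is
attempted; if the resampled means take so few distinct values that the
histogram has fewer than four populated bins (tiny N), a Gaussian fit is
meaningless and empirical moments are reported instead. All resampling is
driven by one integer seed.

Relative rates divide the ligand condition's pooled rate by its matched
reference's; the bootstrap distribution is rescaled by the reference's
Gaussian peak (putting the reference at 1.0), not formed as a ratio of
paired resamples — matching the way normalized rate distributions are
conventionally displayed.

### FRET histograms

Folded-state histograms pool the first `min(15, window)` defined frames per
molecule (the short-movie snapshot practice) into 0.02-wide bins spanning
[−0.2, 1.2]; neither the pooled frame count nor the bin width is prescribed
anywhere authoritative, so both are explicit parameters. Fitting is
least-squares of a sum of Gaussians to the binned counts — the
presentation-style fit, not EM on raw samples — deterministic given the
initial means. Because overlapping peaks (0.59/0.70) create local minima,
the optimiser restarts from a fixed ladder of initial widths (0.02, 0.03,
0.05) and keeps the lowest residual; this remains deterministic.
Components come back sorted by mean with area-fraction weights.
Non-convergence raises an error carrying the residual norm and the
initialization.

## Cumulative-activity assay

Spot detection estimates background statistics robustly (median and scaled
MAD, so the spots themselves do not inflate them), takes local maxima above
`background + 5·SD` within a PSF-sized neighbourhood, and merges maxima
closer than `min_separation` keeping the brighter — making counting
invariant to uniform intensity rescaling. The published counting program is
undescribed, so this detector is an explicit stand-in validated on
synthetic frames only.

Percent remaining normalizes counts to the first snapshot (100%). Relative
activity compares removed fractions `1 − p(t_ref)/100` at `t_ref = 600 s`,
linearly interpolating between the two bracketing time-lapse points since
the snapshot schedule need not hit 600 s exactly. Replicates are
independent series; their sample SD is the reported error. A log-linear
hazard fit through the origin is provided for checking simulated decays.

## Synthetic-data generator

What it emulates:

* two-state continuous-time Markov kinetics (Gillespie-sampled), molecules
  starting folded; conformer assignment parallel/antiparallel/donor-only by
  configured fractions;
* FRET levels 0.70 / 0.59 / 0.12 for the parallel, antiparallel and
  donor-only populations. The unfolded level defaults to 0.30 with the
  overall frame noise ~0.05 — the unfolded distribution is defined only by
  an unavailable supplementary reference construct, so these defaults are
  assumptions chosen to sit clearly below the 0.45 threshold;
* camera integration: the frame straddling a state or bleach boundary
  records the occupancy-weighted mean level (transitions are otherwise
  instantaneous at frame resolution);
* intensity mapping donor = total·(1−E), acceptor = total·E with
  per-channel Gaussian noise (SD 30 counts on a total of 1000) plus
  FRET-scale jitter (SD 0.04) modelling slow conformational/photophysical
  fluctuation — the published data constrain only FRET-scale fidelity, so
  the intensity scale is arbitrary;
* hard single-step photobleaching with exponential lifetimes (defaults
  80 s acceptor, 200 s donor, plausible for cyanine dyes under oxygen
  scavenging at these exposures; `inf` disables);
* spot assay: independent exponential removal and bleach times per spot;
  counts are spots with both times in the future, hence non-increasing;
  frames rendered as symmetric Gaussian PSFs on Gaussian background.

What it does not emulate: dye blinking, spectral crosstalk beyond the
constant donor-leakage level, gradual (multi-frame) unfolding
intermediates, enzyme concentration dependence, surface-quality drift, or
camera pixelation effects beyond integer binning of rendered frames.
Passing recovery tests therefore demonstrates that the analysis is correct
*for data obeying these assumptions*; they cannot certify behaviour on
pathologies the generator omits (e.g. blinking would masquerade as
acceptor bleaching, and gradual transitions would interact with the dwell
rule).

Determinism: each molecule gets a dedicated RNG substream spawned from the
config seed, so conditions reproduce bit-identically and are insensitive to
molecule count changes upstream.

## Problem sizes

The recovery tests and the acceptance script use 500 molecules × 12 000
frames at 50 ms (600 s) for trace-pipeline recovery, 10⁵ frames for
histogram fits, 10⁵ bootstrap sets for the enumeration check and 20 000
elsewhere, and 2000 spots on a 120 s time-lapse grid out to 1200 s — sizes
comparable to the per-condition statistics of the original measurements
(hundreds of molecules, 10⁴ s of cumulative observation).

## Known limitations

* The ground-truth "effective event rate" used in recovery tests counts
  only true events whose unfolded dwell is at least the detector's minimum
  dwell — the rate the counting rule can in principle see. The pooled rate
  therefore underestimates the raw generative hazard by the fraction of
  sub-dwell events, exactly as the conservative rule intends.
* Event-level scoring matches greedily within a frame tolerance; with
  event rates high enough that events crowd within the tolerance it would
  undercount mismatches, so tolerance should stay well below the mean
  inter-event spacing.
* The spot detector reports integer-pixel maxima (no sub-pixel
  localization); positions are accurate to ±1 px per axis, which is
  sufficient for counting.
* `ConditionManifest` pairing is positional: the CLI normalizes every
  ligand condition against the first reference-role manifest of the run,
  reflecting the reference-measured-on-the-same-slide design.
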