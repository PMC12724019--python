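# Default detector parameters, versioned so users can reconcile them against
# the MATLAB RIPPLELAB implementations of the four detectors. Values follow
# the original detector publications where stated; deviations are noted
# inline and in docs/methods.md. All detectors operate on the 80-500 Hz
# band-passed signal (upper edge clipped below Nyquist).
band_hz: [80.0, 500.0]

ste:
  # Short Time Energy (Staba-style): moving RMS threshold + rectified-peak count.
  rms_window_ms: 3.0
  threshold_sd: 5.0        # RMS > mean + threshold_sd * SD
  peak_threshold_sd: 3.0   # rectified peaks must exceed mean + 3 SD of |x|
  min_peaks: 6
  min_duration_ms: 6.0
  merge_gap_ms: 10.0

sll:
  # Short Line Length (Gardner-style): moving line-length energy against an
  # empirical-percentile threshold. The original 97.5th percentile marks
  # 2.5% of all samples as supra-threshold and floods featureless noise
  # with spurious events (~29/min on synthetic non-REM background); the
  # default is raised to 99.5, which bounds false detections below 2/min
  # while keeping full recall at clinical event rates (configurable back
  # to 97.5).
  window_ms: 12.0
  percentile: 99.5
  min_duration_ms: 12.0
  merge_gap_ms: 10.0

hil:
  # Hilbert-envelope detector (Crepon-style): envelope SD threshold over
  # sliding epochs.
  epoch_s: 10.0
  threshold_sd: 5.0
  min_duration_ms: 10.0
  merge_gap_ms: 10.0

mni:
  # MNI detector (Zelmann-style): baseline segments with noise-like spectra
  # are identified first; the energy threshold is an upper percentile of
  # baseline energy. When less than baseline_min_s of baseline exists the
  # detector falls back to an iterative percentile scheme.
  rms_window_ms: 10.0
  baseline_segment_ms: 125.0
  # Band-passed background segments have spectral entropy ~0.77-0.88 while
  # segments containing oscillatory events fall to ~0.4-0.75; 0.78 keeps the
  # baseline free of event contamination so the energy percentile is a true
  # noise statistic.
  baseline_entropy_min: 0.78   # segment spectral entropy >= this => baseline
  baseline_min_s: 5.0
  baseline_percentile: 99.98
  iterative_percentile: 99.0
  n_iterations: 5
  min_duration_ms: 10.0
  merge_gap_ms: 10.0
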