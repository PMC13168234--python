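"""Generate a synthetic ECG record and find its beats.

Builds 30 s of sinus rhythm with occasional PVC-like beats, conditions the
signal with the 0.5-40 Hz bandpass, runs Pan-Tompkins detection, and
compares detections against the generator's ground-truth R times.
"""

import numpy as np

from beatguard import RhythmSpec, bandpass_filter, detect_r_peaks, synth_record

spec = RhythmSpec(duration=30.0, mean_hr_bpm=72.0, pvc_probability=0.15,
                  seed=1)
record, truth = synth_record(spec)
filtered = bandpass_filter(record.samples, record.fs)
peaks = detect_r_peaks(filtered, record.fs)

truth_idx = np.round(truth.r_times * record.fs).astype(int)
tol = int(0.025 * record.fs)  # 25 ms matching tolerance
hits = sum(np.min(np.abs(peaks - t)) <= tol for t in truth_idx)

print(f"simulated beats: {len(truth_idx)} "
      f"({truth.labels.count('V')} PVC-like)")
print(f"detected peaks:  {len(peaks)}")
print(f"matched within 25 ms: {hits}/{len(truth_idx)}")
# All beats should be matched: on clean synthetic rhythms the detector
# recovers every R-peak to within a couple of samples.
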