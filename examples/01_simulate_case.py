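"""Generate a synthetic EEG case and inspect its spatial ground truth.

Builds a CHB-MIT-style case (4 files at 256 Hz, 2 containing seizures,
ictal bursts dominant on one wearable derivation), then measures 4-6 Hz
band power on every bipolar channel inside the first seizure to show the
spatial localization the single-channel detector relies on.
"""

import numpy as np
from scipy.signal import welch

import monoseize as ms

case = ms.generate_case(ms.SynthConfig(seed=7, ictal_freq_hz=(4.5, 5.5)))
print(f"case {case.manifest_row['case_id']}: "
      f"{case.manifest_row['n_seizures']} seizures, "
      f"{case.manifest_row['recording_length_h']:.2f} h total, "
      f"dominant channel {case.ground_truth_channel}")

rec, ann = case.recordings[0], case.annotations[0]
bip = ms.apply_montage(rec)
onset, offset = ann.intervals[0]
i0, i1 = int(onset * rec.fs), int(offset * rec.fs)

print(f"\n4-6 Hz band power during seizure [{onset:.0f}s, {offset:.0f}s):")
for label, row in zip(bip.channel_labels, bip.signal):
    f, p = welch(row[i0:i1], fs=rec.fs, nperseg=1024)
    power = np.trapezoid(p[(f >= 4) & (f <= 6)], f[(f >= 4) & (f <= 6)])
    marker = "  <-- dominant" if label == case.ground_truth_channel else ""
    print(f"  {label:8s} {power:10.1f} uV^2/Hz{marker}")

# The dominant derivation carries the full burst amplitude; neighbours get
# at most spatial_attenuation (0.5) of it, i.e. ~1/4 of the band power.
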