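"""Write an annotated multi-channel EDF recording and cut it into windows.

Demonstrates the clinical segmentation rules: 2-s sliding ictal windows with
50% overlap inside each seizure, and non-overlapping 2-s interictal epochs
taken at least `gap_s` away from every seizure.
"""

import tempfile
from pathlib import Path

from szpipe.signal_io import (extract_ictal_windows, extract_interictal_epochs,
                              read_annotation_csv, read_edf_recording)
from szpipe.synthdata import SynthConfig, gen_annotated_recording

cfg = SynthConfig(fs=256.0, n_channels=4, seed=3)
outdir = Path(tempfile.mkdtemp())
edf, csv = outdir / "recording.edf", outdir / "annotations.csv"

_, ann = gen_annotated_recording(cfg, n_seizures=2, durations_s=[12, 9],
                                 total_s=300.0, edf_path=edf, csv_path=csv)
rec = read_edf_recording(edf)
ann = read_annotation_csv(csv, recording_length_s=300.0)
print(f"recording: {rec.n_channels} channels x {rec.n_timepoints} samples "
      f"@ {rec.fs:.0f} Hz")
print("seizures:", ann.events)

ictal = extract_ictal_windows(rec, ann, win_s=2.0, step_s=1.0)
inter = extract_interictal_epochs(rec, ann, win_s=2.0, gap_s=60.0)
print(f"{len(ictal)} ictal windows (= sum of duration-1 per seizure), "
      f"{len(inter)} interictal epochs >= 60 s from any seizure")

# A 12-s and a 9-s seizure yield 11 + 8 = 19 overlapping ictal windows; the
# interictal epochs tile the remaining distant stretches without overlap.
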