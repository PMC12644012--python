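"""Band-pass filtering and DWT sub-band feature extraction on one segment.

Shows the 0.5-60 Hz 5th-order Butterworth preprocessing, the five-level db4
decomposition with its dyadic band edges, and the 24 features (6 sub-bands x
MAV/STD/PSD/FuEn) a single-channel segment contributes to the feature table.
"""

from szpipe.features import BAND_ORDER, build_feature_table, dwt_decompose
from szpipe.signal_io import FilterSpec, bandpass_filter
from szpipe.synthdata import SynthConfig, gen_dataset

cfg = SynthConfig(n_interictal=1, n_ictal=1, seed=0)
raw = gen_dataset(cfg)
filtered = [bandpass_filter(s, FilterSpec(0.5, 60.0, order=5)) for s in raw]

dec = dwt_decompose(filtered[0].samples[0], fs=cfg.fs)
print("sub-band edges (Hz):")
for band in BAND_ORDER:
    lo, hi = dec.band_edges_hz[band]
    print(f"  {band}: {lo:6.2f} - {hi:6.2f}  ({len(dec.bands[band])} coefficients)")

table = build_feature_table(filtered)
print(f"\nfeature table: {table.n_rows} x {table.n_features}")
for label in ("ictal", "interictal"):
    row = table.values[table.labels == label][0]
    cols = {str(c): v for c, v in zip(table.columns, row) if c.band == "D3"}
    print(label, {k.split('|', 1)[1]: round(v, 2) for k, v in cols.items()})

# D3-band MAV/STD/PSD/FuEn are all larger for the ictal window - the
# separation the downstream classifier exploits.
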