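"""Generate synthetic sinus-rhythm and fibrillation beat streams.

Builds one NSR and one AFIB RR-interval sequence with the generator's
default physiology and prints the summary statistics that make the two
rhythms separable: fibrillation has much larger beat-to-beat variability
(RMSSD) and essentially no serial correlation between successive intervals.
"""
import numpy as np

from afibkit import SyntheticSpec, generate_rr

for rhythm in ("NSR", "AFIB"):
    spec = SyntheticSpec(rhythm=rhythm, duration_s=120.0, seed=42)
    rr = generate_rr(spec)
    rmssd = np.sqrt(np.mean(np.diff(rr) ** 2))
    lag1 = np.corrcoef(rr[:-1], rr[1:])[0, 1]
    print(
        f"{rhythm}: {len(rr)} beats, mean RR {rr.mean():.0f} ms, "
        f"RMSSD {rmssd:.1f} ms, lag-1 correlation {lag1:+.2f}"
    )

print(
    "\nRMSSD an order of magnitude larger and near-zero lag-1 correlation "
    "are the fibrillation signatures both detectors rely on."
)
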