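"""Enumerate a small virtual compound set and look at its size
distribution.

Grows 2,000 molecules from a single carbon atom using the default
ten-fragment C/H/N/O library with the calibrated growth settings, then
prints the molecular-weight distribution.  The mean should sit near
264 g/mol with an SD near 65 — the calibration target of the default
configuration.
"""

import numpy as np

from enumol import EnumeratorConfig, enumerate_set

config = EnumeratorConfig()
records = list(enumerate_set(config, 2000, master_seed=42))

mws = np.array([r.mw for r in records])
print("first five molecules:")
for rec in records[:5]:
    print(f"  {rec.smiles}  (MW {rec.mw:.1f})")
print(f"\nn = {len(records)}")
print(f"mean MW = {mws.mean():.1f} g/mol  (calibration target 264)")
print(f"SD MW   = {mws.std():.1f} g/mol  (calibration target 65)")
print(f"MW < 500: {np.mean(mws < 500) * 100:.1f}% of molecules")
print("\nSame seed + config always reproduces these molecules exactly;")
print("each record is independently reproducible from (seed, index).")
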