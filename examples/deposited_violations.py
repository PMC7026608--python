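"""Critical-NOE violation report for a deposited multi-model NMR entry.

Usage:  python examples/deposited_violations.py path/to/5lsn.pdb

The package ships the critical-NOE panel of the 29-nt hairpin system
(pairs whose relative signal dips below 1.2 in at least one ensemble,
with their strong/medium/weak classes).  Given the deposited entry --
e.g. fetched once with
``curl -O https://files.rcsb.org/download/5LSN.pdb`` -- this prints the
relative average signals <f(d)>/f(d_exp) per proton pair for the seven
chi16 = 100-degree models; values below 1 are violated upper bounds.
"""

import sys

from noeme import Ensemble, build_signal_matrix, read_multimodel_pdb, relative_signals, violation_report
from noeme.geometry import chi_angle
from noeme.noe import load_critical_panel

if len(sys.argv) != 2:
    sys.exit(__doc__)

ensemble = read_multimodel_pdb(sys.argv[1])
print(f"models parsed: {len(ensemble)}")

# split the bundle on the glycosidic angle of loop residue 16
chis = [chi_angle(s, 16) for s in ensemble]
nmr1 = Ensemble([s for s, c in zip(ensemble, chis) if abs(c - 100) <= 15])
print(f"chi16 per model: {[round(c) for c in chis]}")
print(f"models with chi16 = 100 +- 15 deg: {len(nmr1)}")

panel = load_critical_panel()
ratios = relative_signals(build_signal_matrix(nmr1, panel), panel)
report = violation_report(panel, ratios)
print(report.to_string(index=False))
print(f"\nviolated upper bounds: {int(report.violated.sum())}")
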