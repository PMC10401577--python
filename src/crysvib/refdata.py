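"""Reference data: published DFT-optimized unit-cell parameters of the four
L-cysteine polymorphs at their experimental pressures.

Used as worked-example input for the closed-form cell-volume bookkeeping
(`cell_volume`) and by the examples; the printed volumes are three-decimal
rounded, so recomputed volumes agree within ~0.1 Å³.
"""

from __future__ import annotations

import pandas as pd

#: columns: polymorph, P (GPa), a, b, c (Å), alpha, beta, gamma (deg),
#: volume (Å³, as printed), energy (eV/cell, as printed)
CYSTEINE_CELLS = pd.DataFrame(
    [
        ("Form I", 0.0, 8.087, 11.900, 5.421, 90.0, 90.0, 90.0, 521.65, -323.555),
        ("Form II", 0.0, 9.438, 5.199, 11.218, 90.0, 109.0, 90.0, 520.48, -323.464),
        ("Form III", 2.6, 7.949, 10.511, 5.348, 90.0, 90.0, 90.0, 446.83, -322.858),
        ("Form III", 4.2, 7.874, 10.315, 5.288, 90.0, 90.0, 90.0, 429.46, -322.456),
        ("Form IV", 1.7, 8.073, 5.402, 10.927, 90.0, 95.8, 90.0, 474.08, -323.157),
    ],
    columns=["polymorph", "P_GPa", "a", "b", "c", "alpha", "beta", "gamma",
             "volume_A3", "energy_eV"],
)

#: thiol C–C–S–H dihedral angles (degrees) characterizing the two
#: hydrogen-bond motifs in the ordered/disordered Form I structures:
#: neutron values at room temperature and the dispersed-disorder build angles
MOTIF_ANGLES = {
    "SH...S_neutron_293K": 77.6,
    "SH...O_neutron_293K": -85.4,
    "SH...S_build": 87.0,
    "SH...O_build": -78.4,
}
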