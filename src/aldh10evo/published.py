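"""Reported steady-state kinetic parameters for spinach BADH A441 variants.

These are the published wild-type and position-441 mutant parameters for the
oxidation of betaine aldehyde (BAL) and 3-aminopropionaldehyde (APAL), each
block measured at pH 8.0, 30 °C, with the co-substrate fixed (0.2 mM NAD+
for the aldehyde blocks; aldehyde at 10x Km for the NAD+ blocks).  They are
inputs to the analysis: the catalytic-efficiency consistency sweep and the
two-group BADH classification both start from these numbers.

Columns: kcat (s^-1), kcat_err, Km (µM), Km_err, eff (kcat/Km, mM^-1 s^-1)
as printed, eff_err, and eff_decimals — the number of decimals the printed
efficiency carries, which sets the unit-in-the-last-place used when checking
arithmetic consistency against re-derived values.
"""

from __future__ import annotations

import pandas as pd

VARIANTS = ["wild-type", "A441C", "A441S", "A441T", "A441V", "A441F", "A441I"]

_COLS = ["variant", "kcat", "kcat_err", "Km", "Km_err", "eff", "eff_err",
         "eff_decimals"]

#: BAL saturation kinetics (variable substrate betaine aldehyde).
BAL_KINETICS = pd.DataFrame([
    ("wild-type", 3.36, 0.13, 98.0, 15.0, 35.0, 4.0, 0),
    ("A441C", 2.99, 0.19, 90.0, 6.0, 33.0, 2.0, 0),
    ("A441S", 3.29, 0.12, 119.0, 8.0, 28.0, 3.0, 0),
    ("A441T", 2.64, 0.16, 180.0, 6.0, 15.0, 1.0, 0),
    ("A441V", 0.54, 0.05, 512.0, 79.0, 1.1, 0.3, 1),
    ("A441F", 0.29, 0.02, 605.0, 26.0, 0.48, 0.05, 2),
    ("A441I", 0.74, 0.05, 1791.0, 115.0, 0.41, 0.05, 2),
], columns=_COLS)

#: NAD+ saturation kinetics with BAL as the fixed aldehyde.
BAL_NAD_KINETICS = pd.DataFrame([
    ("wild-type", 4.25, 0.16, 22.0, 2.0, 195.0, 8.0, 0),
    ("A441C", 2.20, 0.09, 14.0, 1.0, 179.0, 17.0, 0),
    ("A441S", 3.27, 0.18, 29.0, 3.0, 114.0, 20.0, 0),
    ("A441T", 2.39, 0.00, 24.0, 4.0, 100.0, 15.0, 0),
    ("A441V", 0.51, 0.00, 6.4, 0.5, 80.0, 5.0, 0),
    ("A441F", 0.39, 0.02, 18.0, 1.0, 22.0, 0.0, 0),
    ("A441I", 0.68, 0.03, 2.8, 0.0, 243.0, 11.0, 0),
], columns=_COLS)

#: APAL saturation kinetics (variable substrate 3-aminopropionaldehyde).
#: APAL shows substrate inhibition; the printed kcat/Km come from the
#: total-inhibition rate law, but the inhibition constants themselves were
#: not identifiable at the concentrations assayed and were not reported.
APAL_KINETICS = pd.DataFrame([
    ("wild-type", 0.99, 0.04, 3.9, 0.1, 256.0, 5.0, 0),
    ("A441C", 0.67, 0.02, 0.72, 0.16, 931.0, 188.0, 0),
    ("A441S", 1.12, 0.00, 2.0, 0.5, 550.0, 142.0, 0),
    ("A441T", 1.50, 0.12, 4.6, 0.5, 326.0, 13.0, 0),
    ("A441V", 0.52, 0.10, 1.1, 0.3, 473.0, 216.0, 0),
    ("A441F", 0.34, 0.04, 3.7, 0.0, 92.0, 11.0, 0),
    ("A441I", 1.85, 0.06, 4.8, 1.3, 375.0, 80.0, 0),
], columns=_COLS)

#: NAD+ saturation kinetics with APAL as the fixed aldehyde.
APAL_NAD_KINETICS = pd.DataFrame([
    ("wild-type", 0.99, 0.04, 4.0, 0.1, 250.0, 7.0, 0),
    ("A441C", 0.89, 0.00, 2.6, 0.5, 342.0, 76.0, 0),
    ("A441S", 0.88, 0.02, 2.8, 0.0, 314.0, 13.0, 0),
    ("A441T", 0.76, 0.02, 4.0, 0.4, 190.0, 16.0, 0),
    ("A441V", 0.54, 0.06, 1.7, 0.2, 318.0, 2.0, 0),
    ("A441F", 0.43, 0.01, 5.9, 1.4, 73.0, 17.0, 0),
    ("A441I", 2.11, 0.01, 5.5, 0.1, 382.0, 9.0, 0),
], columns=_COLS)

ALL_KINETIC_TABLES = {
    "BAL": BAL_KINETICS,
    "BAL/NAD+": BAL_NAD_KINETICS,
    "APAL": APAL_KINETICS,
    "APAL/NAD+": APAL_NAD_KINETICS,
}


def bal_efficiencies() -> dict[str, float]:
    """Printed kcat/Km (mM^-1 s^-1) with BAL, keyed by variant."""
    return dict(zip(BAL_KINETICS["variant"], BAL_KINETICS["eff"]))
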