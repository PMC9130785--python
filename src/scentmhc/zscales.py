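"""Amino-acid z-scale physico-chemical descriptors.

The five z-scales of Sandberg et al. (1998, J. Med. Chem. 41:2481-2491)
summarize amino-acid physico-chemistry as principal properties derived
from a large panel of experimental and computed variables:

* z1 -- lipophilicity / hydrophobicity (negative = hydrophobic)
* z2 -- steric bulk and polarizability
* z3 -- polarity / charge
* z4, z5 -- electronic effects (electronegativity, heat of formation,
  electrophilicity)

The table below covers the 20 standard proteinogenic residues
(one-letter codes) and is shipped as a versioned constant; analyses may
substitute any user-supplied table with the same shape.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Descriptor column names, in canonical order.
Z_COLUMNS = ("z1", "z2", "z3", "z4", "z5")

# Sandberg et al. (1998) table 2, 20 coded amino acids.
_Z_SCALES = {
    #        z1     z2     z3     z4     z5
    "A": (0.24, -2.32, 0.60, -0.14, 1.30),
    "R": (3.52, 2.50, -3.50, 1.99, -0.17),
    "N": (3.05, 1.62, 1.04, -1.15, 1.61),
    "D": (3.98, 0.93, 1.93, -2.46, 0.75),
    "C": (0.84, -1.67, 3.71, 0.18, -2.65),
    "Q": (1.75, 0.50, -1.44, -1.34, 0.66),
    "E": (3.11, 0.26, -0.11, -3.04, -0.25),
    "G": (2.05, -4.06, 0.36, -0.82, -0.38),
    "H": (2.47, 1.95, 0.26, 3.90, 0.09),
    "I": (-3.89, -1.73, -1.71, -0.84, 0.26),
    "L": (-4.28, -1.30, -1.49, -0.72, 0.84),
    "K": (2.29, 0.89, -2.49, 1.49, 0.31),
    "M": (-2.85, -0.22, 0.47, 1.94, -0.98),
    "F": (-4.22, 1.94, 1.06, 0.54, -0.62),
    "P": (-1.66, 0.27, 1.84, 0.70, 2.00),
    "S": (2.39, -1.07, 1.15, -1.39, 0.67),
    "T": (0.75, -2.18, -1.12, -1.46, -0.40),
    "W": (-4.36, 3.94, 0.59, 3.44, -1.59),
    "Y": (-2.54, 2.44, 0.43, 0.04, -1.47),
    "V": (-2.59, -2.64, -1.54, -0.85, -0.02),
}

#: The 20 standard residues, alphabetical by one-letter code.
STANDARD_RESIDUES = tuple(sorted(_Z_SCALES))


def z_descriptor_table() -> pd.DataFrame:
    """Return the 20x5 z-descriptor table as a DataFrame.

    Rows are indexed by one-letter residue code (alphabetical), columns
    are ``z1..z5``. The returned frame is a fresh copy: callers may
    mutate it to build custom descriptor sets.
    """
    return pd.DataFrame.from_dict(_Z_SCALES, orient="index", columns=list(Z_COLUMNS)).sort_index()


def validate_descriptor_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a user-supplied descriptor table and return it normalized.

    Requirements: exactly 20 standard residues in the index, all five
    z-columns present, every entry finite.
    """
    missing_cols = [c for c in Z_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"descriptor table missing columns: {missing_cols}")
    idx = set(table.index)
    expected = set(STANDARD_RESIDUES)
    if idx != expected:
        extra = sorted(idx - expected)
        missing = sorted(expected - idx)
        raise ValueError(
            f"descriptor table must cover the 20 standard residues; "
            f"missing={missing} unexpected={extra}"
        )
    tab = table.loc[list(STANDARD_RESIDUES), list(Z_COLUMNS)].astype(float)
    if not np.isfinite(tab.to_numpy()).all():
        raise ValueError("descriptor table contains non-finite entries")
    return tab
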