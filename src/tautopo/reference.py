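"""Published reference data for the 17 deposited tau filament structures.

Global topological metrics (normalized writhe Wr/N, normalized stacked-
filament linking Lk_s/N, absolute second Vassiliev measure |V2|; all in
multiples of 1e-3) as reported for the cryo-EM tau filament dataset, plus the
repeat-pair linking sign tuples derived from the published repeat linking
table.  These serve as typed-in inputs for the clustering and classification
examples and as cross-checks for the pipeline; they are not computed here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["FILAMENTS", "global_metrics", "sign_tuples"]

#: filament id -> (disease group, PDB accession, Wr/N, Lk_s/N, |V2|), the
#: three metrics in multiples of 1e-3.
FILAMENTS: dict[str, tuple[str, str, float, float, float]] = {
    "AD-SF":    ("AD",   "5o3t", -3.65,  0.990, 0.640),
    "AD-PHF":   ("AD",   "5o3l", -3.59,  1.15,  0.585),
    "PART":     ("PART", "7nrq", -0.350, 1.41,  0.765),
    "CTE-I":    ("CTE",  "6nwp", -0.269, 1.06,  0.255),
    "CTE-II":   ("CTE",  "6nwq", -0.104, 0.904, 0.360),
    "PiD":      ("PiD",  "6gx5", -1.02,  0.145, 0.130),
    "CBD-I":    ("CBD",  "6tjo", -0.154, 0.627, 1.05),
    "CBD-II":   ("CBD",  "6tjx",  0.603, 0.518, 1.06),
    "AGD-I":    ("AGD",  "7p6d",  1.26,  0.649, 0.620),
    "AGD-II":   ("AGD",  "7p6e",  0.325, 0.303, 1.43),
    "PSP":      ("PSP",  "7p65",  2.79,  1.26,  2.69),
    "GGT-I":    ("GGT",  "7p66",  3.68,  0.642, 0.105),
    "GGT-II":   ("GGT",  "7p67",  4.28,  0.590, 0.300),
    "GGT-III":  ("GGT",  "7p68",  3.68,  0.138, 0.205),
    "GPT-Ia":   ("GPT",  "7p6a",  1.71,  0.001, 2.39),
    "GPT-Ib":   ("GPT",  "7p6b",  0.986, 0.688, 0.150),
    "GPT-II":   ("GPT",  "7p6c",  1.15,  0.174, 2.54),
}

#: Signs of the repeat-pair linking numbers (order: R2-R3, R2-R4, R2-C,
#: R3-R4, R3-C, R4-C; then the R1 pairs R1-R3, R1-R4, R1-C), as strings over
#: {+,-,0} with 0 meaning ND.
SIGN_TUPLES: dict[str, tuple[str, str]] = {
    "AD-SF":   ("000---", "000"),
    "AD-PHF":  ("000---", "000"),
    "PART":    ("000---", "000"),
    "CTE-I":   ("000---", "000"),
    "CTE-II":  ("000---", "000"),
    "PiD":     ("000-+-", "-+-"),
    "CBD-I":   ("+++--+", "000"),
    "CBD-II":  ("+++--+", "000"),
    "AGD-I":   ("+++--+", "000"),
    "AGD-II":  ("+++---", "000"),
    "PSP":     ("+-++++", "000"),
    "GGT-I":   ("+-++-+", "000"),
    "GGT-II":  ("+-++-+", "000"),
    "GGT-III": ("+-++-+", "000"),
    "GPT-Ia":  ("-++--+", "000"),
    "GPT-Ib":  ("+-++-+", "000"),
    "GPT-II":  ("--++-+", "000"),
}


def global_metrics() -> pd.DataFrame:
    """The published global metrics as a DataFrame indexed by filament id.

    Columns ``wr_per_n``, ``lks_per_n``, ``abs_v2`` are in multiples of 1e-3,
    as printed; ``group`` and ``accession`` identify the filaments.
    """
    rows = [(fid, g, acc, wr, lks, v2)
            for fid, (g, acc, wr, lks, v2) in FILAMENTS.items()]
    return pd.DataFrame(rows, columns=["filament", "group", "accession",
                                       "wr_per_n", "lks_per_n", "abs_v2"]
                        ).set_index("filament")


def sign_tuples():
    """Published repeat-pair sign tuples as :class:`SignTuple` objects."""
    from .fingerprints import SignTuple
    conv = {"+": 1, "-": -1, "0": None}
    return {fid: SignTuple(main=tuple(conv[c] for c in main),
                           extra=tuple(conv[c] for c in extra))
            for fid, (main, extra) in SIGN_TUPLES.items()}
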