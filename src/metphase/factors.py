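"""Random-term vocabulary shared by the simulator and the mixed model.

Each term names a non-genetic source of variation from either the field
phase (``F_`` prefix) or the laboratory phase (``L_`` prefix).  A term maps
every observation (one well) to a factor level; observations sharing a
level share one random-effect draw.
"""

from __future__ import annotations

import pandas as pd

#: All recognised field/laboratory random terms.
TERM_VOCABULARY: tuple[str, ...] = (
    "F_block",
    "F_row",
    "F_column",
    "F_rowxcol",
    "L_day",
    "L_dayxplate",
    "L_platexplot",
    "L_column",
    "L_row",
    "L_platexcolumn",
    "L_platexrow",
    "L_rowxcol",
)

FIELD_TERMS = tuple(t for t in TERM_VOCABULARY if t.startswith("F_"))
LAB_TERMS = tuple(t for t in TERM_VOCABULARY if t.startswith("L_"))

_REQUIRED = {
    "F_block": ("block",),
    "F_row": ("field_row",),
    "F_column": ("field_column",),
    "F_rowxcol": ("field_row", "field_column"),
    "L_day": ("day",),
    "L_dayxplate": ("day", "plate"),
    "L_platexplot": ("plate", "plate_plot"),
    "L_column": ("plate_column",),
    "L_row": ("plate_row",),
    "L_platexcolumn": ("plate", "plate_column"),
    "L_platexrow": ("plate", "plate_row"),
    "L_rowxcol": ("plate_row", "plate_column"),
}


def is_field_term(term: str) -> bool:
    return term.startswith("F_")


def term_levels(df: pd.DataFrame, term: str) -> pd.Series:
    """Return the factor level of ``term`` for every row of ``df``.

    Levels are strings; interaction terms join their parent levels with
    ``":"``.  Raises ``KeyError`` for an unknown term and ``ValueError``
    if a required factor column is missing.
    """
    if term not in _REQUIRED:
        raise KeyError(f"unknown random term {term!r}")
    cols = _REQUIRED[term]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"term {term!r} needs missing column(s) {missing}")
    if len(cols) == 1:
        return df[cols[0]].astype(str)
    out = df[cols[0]].astype(str)
    for c in cols[1:]:
        out = out + ":" + df[c].astype(str)
    return out
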