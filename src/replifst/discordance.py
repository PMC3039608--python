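"""Cramer's phi: discordance of replicability between two continents.

For each association studied in both Europe and East Asia, a 2x2 table
crosses continent against study outcome (positive / negative).  Cramer's
phi for that table is 0 when the proportion of positive studies is the
same on both continents and 1 when one continent replicated always and the
other never -- a direct index of how discordant the two bodies of
literature are.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = ["cramers_phi", "continental_contingency", "add_phi"]


def cramers_phi(table) -> float:
    """Cramer's phi of a 2x2 contingency table.

    ``phi = |ad - bc| / sqrt((a+b)(c+d)(a+c)(b+d))`` for the table
    ``[[a, b], [c, d]]``; algebraically identical to
    ``sqrt(chi2_uncorrected / N)``.  A table with a zero margin (e.g. every
    study positive on both continents) carries no evidence of discordance
    and returns 0 by convention.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("contingency cells must be non-negative")
    if t.sum() < 1:
        raise ValueError("contingency table is empty")
    (a, b), (c, d) = t
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return float(abs(a * d - b * c) / math.sqrt(denom))


def continental_contingency(summary) -> np.ndarray:
    """Build the continent x outcome table from one association summary.

    ``summary`` is any mapping (a Series or dict) carrying
    ``n_studies_eur, n_positive_eur, n_studies_eas, n_positive_eas``.
    Rows are (Europe, EastAsia), columns (positive, negative).
    """
    n_eur = int(summary["n_studies_eur"])
    n_eas = int(summary["n_studies_eas"])
    if n_eur == 0 or n_eas == 0:
        raise ValueError("association has no studies in one continent")
    pos_eur = int(summary["n_positive_eur"])
    pos_eas = int(summary["n_positive_eas"])
    if pos_eur > n_eur or pos_eas > n_eas:
        raise ValueError("positive count exceeds study count")
    return np.array(
        [[pos_eur, n_eur - pos_eur], [pos_eas, n_eas - pos_eas]], dtype=int
    )


def add_phi(summaries: pd.DataFrame) -> pd.DataFrame:
    """Append a ``phi`` column to a Continental-Set summary table."""
    out = summaries.copy()
    out["phi"] = [
        cramers_phi(continental_contingency(row))
        for _, row in summaries.iterrows()
    ]
    return out
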