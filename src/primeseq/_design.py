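"""Design matrices with treatment (reference-level) coding.

Terms are factor names (``"exercise"``) or two-way interactions written
``"a:b"``.  Reference levels follow the closed factor vocabularies
(SED, none, L, simultaneous come first); unknown factors use sorted level
order with the first level as reference.  The intercept is always included.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REFERENCE_ORDER = {
    "exercise": ["SED", "ELE"],
    "learning": ["none", "3min", "10min"],
    "hemisphere": ["L", "R", "both"],
    "isolation": ["simultaneous", "separate"],
}


def factor_levels(design: pd.DataFrame, factor: str) -> list[str]:
    observed = list(pd.unique(design[factor]))
    preferred = REFERENCE_ORDER.get(factor)
    if preferred:
        ordered = [lv for lv in preferred if lv in observed]
        ordered += sorted(set(observed) - set(ordered))
        return ordered
    return sorted(observed)


def _main_effect_columns(design: pd.DataFrame, factor: str):
    levels = factor_levels(design, factor)
    cols, names = [], []
    for lv in levels[1:]:
        cols.append((design[factor] == lv).to_numpy(dtype=float))
        names.append(f"{factor}[{lv}]")
    return cols, names


def build_design_matrix(
    design: pd.DataFrame, terms: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Return (X, column_names) for intercept + the given terms in order."""
    n = len(design)
    cols = [np.ones(n)]
    names = ["Intercept"]
    for term in terms:
        if ":" in term:
            a, b = term.split(":")
            a_cols, a_names = _main_effect_columns(design, a.strip())
            b_cols, b_names = _main_effect_columns(design, b.strip())
            for ac, an in zip(a_cols, a_names):
                for bc, bn in zip(b_cols, b_names):
                    cols.append(ac * bc)
                    names.append(f"{an}:{bn}")
        else:
            c, nms = _main_effect_columns(design, term.strip())
            cols.extend(c)
            names.extend(nms)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"design matrix for terms {terms} is rank deficient")
    return X, names


def parse_terms(formula: str) -> list[str]:
    """Split ``"a + b + a:b"`` into a term list."""
    return [t.strip() for t in formula.split("+") if t.strip()]
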