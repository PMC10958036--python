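"""Inter-rater agreement on scan-level diagnoses.

A cohort of scans is diagnosed independently by several
histopathologists and by the automated rule, each giving one of NC
(non-cancerous), IHC (uncertain, needs further examination) or C
(cancerous).  Agreement between every pair of raters (and between
each rater and the rule) is measured with Spearman's rank correlation
on the ordinal encoding NC < IHC < C; the coefficient depends only on
that order, and IHC naturally sits between the two definite calls.

A transcribed 46-scan prostate-biopsy reference cohort with nine
expert raters, the automated rule's cancer-tissue percentage and its
output label ships with the package
(``data/diagnosis_cohort_46.csv``) and backs the test suite.
"""

from __future__ import annotations

import warnings
from importlib import resources
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scan_diagnosis import DIAGNOSES

#: ordinal severity encoding of the three diagnosis labels
LABEL_CODES = {"NC": 0, "IHC": 1, "C": 2}

FIXTURE_NAME = "diagnosis_cohort_46.csv"


def encode_labels(labels: Sequence[str]) -> np.ndarray:
    """Map NC/IHC/C to 0/1/2; unknown labels are rejected."""
    out = np.empty(len(labels), dtype=float)
    for i, lab in enumerate(labels):
        if lab not in LABEL_CODES:
            raise ValueError(f"unknown diagnosis label {lab!r} at position {i}")
        out[i] = LABEL_CODES[lab]
    return out


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (mid-ranks for ties).

    Undefined (NaN, with a warning) when either input has zero
    variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("inputs must be equal-length with at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero-variance input: Spearman correlation undefined")
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round half away from zero (reporting convention)."""
    factor = 10**decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def load_diagnosis_table(path: Optional[str | Path] = None) -> pd.DataFrame:
    """Load a diagnosis cohort table (default: the packaged 46-scan cohort).

    Columns: ``scan_id``, rater columns (``D1``..), ``c_tissue_pct``
    and ``model`` (the automated rule's label).
    """
    if path is None:
        source = resources.files("wsidiag").joinpath(f"data/{FIXTURE_NAME}")
        with resources.as_file(source) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    label_cols = [c for c in df.columns if c not in ("scan_id", "c_tissue_pct")]
    for col in label_cols:
        bad = set(df[col]) - set(DIAGNOSES)
        if bad:
            raise ValueError(f"column {col!r} contains invalid labels {sorted(bad)}")
    if "c_tissue_pct" in df.columns:
        pct = df["c_tissue_pct"]
        if ((pct < 0) | (pct > 100)).any():
            raise ValueError("c_tissue_pct outside [0, 100]")
    return df


def rater_columns(table: pd.DataFrame, rule_col: str = "model") -> List[str]:
    return [
        c
        for c in table.columns
        if c not in ("scan_id", "c_tissue_pct", rule_col)
    ]


def agreement_matrix(
    table: pd.DataFrame,
    columns: Optional[Sequence[str]] = None,
    rule_col: str = "model",
    decimals: int = 2,
) -> pd.DataFrame:
    """Pairwise Spearman coefficients over raters and the rule.

    Returns a symmetric matrix with unit diagonal, rounded half away
    from zero to ``decimals``; undefined pairs propagate as NaN.
    """
    if columns is None:
        columns = rater_columns(table, rule_col)
        if rule_col in table.columns:
            columns = list(columns) + [rule_col]
    encoded = {col: encode_labels(list(table[col])) for col in columns}
    n = len(columns)
    mat = np.full((n, n), np.nan)
    for i in range(n):
        mat[i, i] = 1.0
        for j in range(i):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rho = spearman(encoded[columns[i]], encoded[columns[j]])
            if not np.isnan(rho):
                rho = round_half_away(rho, decimals)
            mat[i, j] = mat[j, i] = rho
    return pd.DataFrame(mat, index=list(columns), columns=list(columns))
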