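"""Group comparisons and PCA of the structural predictors.

Tolerated and non-tolerated deletions are compared per predictor with
Welch two-sample t-tests, the secondary-structure composition with a 2x3
Pearson chi-squared contingency test, and the joint covariation of the
predictors with a correlation-matrix PCA (each encoded column centered and
unit-scaled before eigendecomposition).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .exceptions import DegenerateTableError, EncodingError

logger = logging.getLogger(__name__)

SS_ORDER = ("loop", "helix", "sheet")
GROUP_ORDER = ("tolerated", "non_tolerated")


@dataclass
class GroupTTest:
    """Welch t-test between tolerated and non-tolerated groups."""

    statistic: float
    pvalue: float
    mean_tolerated: float
    mean_non_tolerated: float
    n_tolerated: int
    n_non_tolerated: int


def group_t_test(
    values: Sequence[float], labels: Sequence[bool]
) -> GroupTTest:
    """Two-sided Welch (unequal-variance) t-test of values by label.

    ``labels`` is the functional indicator (True = tolerated); the
    statistic is oriented tolerated minus non-tolerated.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = values[labels]
    neg = values[~labels]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("each group needs at least 2 values")
    t, p = scipy.stats.ttest_ind(pos, neg, equal_var=False)
    return GroupTTest(
        statistic=float(t),
        pvalue=float(p),
        mean_tolerated=float(pos.mean()),
        mean_non_tolerated=float(neg.mean()),
        n_tolerated=len(pos),
        n_non_tolerated=len(neg),
    )


@dataclass
class ContingencyTable:
    """2x3 counts of {tolerated, non-tolerated} x {loop, helix, sheet}."""

    counts: pd.DataFrame  # rows GROUP_ORDER, columns SS_ORDER
    tolerated_fractions: pd.Series  # per SS category

    @property
    def values(self) -> np.ndarray:
        return self.counts.to_numpy()


def ss_contingency(table: pd.DataFrame) -> ContingencyTable:
    """Cross-tabulate functional status against secondary structure.

    Also reports, per secondary-structure category, the fraction of
    deletions that are tolerated (the quantity plotted in the standard
    stacked-bar comparison).
    """
    unknown = set(table["ss"]) - set(SS_ORDER)
    if unknown:
        raise ValueError(f"unknown secondary-structure categories: {unknown}")
    counts = pd.DataFrame(
        0, index=list(GROUP_ORDER), columns=list(SS_ORDER), dtype=int
    )
    for _, row in table.iterrows():
        group = "tolerated" if bool(row["functional"]) else "non_tolerated"
        counts.loc[group, row["ss"]] += 1
    totals = counts.sum(axis=0)
    with np.errstate(invalid="ignore"):
        fractions = counts.loc["tolerated"] / totals.replace(0, np.nan)
    return ContingencyTable(counts=counts, tolerated_fractions=fractions)


def chi_square_test(
    contingency: ContingencyTable,
) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence (no continuity correction).

    Returns ``(statistic, dof, pvalue)`` with dof = (rows-1)(cols-1).
    Categories with zero marginal counts make expected counts zero and
    raise a degenerate-table error.
    """
    counts = contingency.values
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise DegenerateTableError(
            "zero marginal in contingency table; drop the empty category"
        )
    res = scipy.stats.chi2_contingency(counts, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


@dataclass
class PCAResult:
    """Correlation-matrix PCA of the encoded predictors.

    ``rotation`` holds the principal axes as columns (orthonormal over the
    retained input columns); ``explained_variance`` are the eigenvalues of
    the correlation matrix (they sum to the number of retained columns);
    ``scores`` are the per-mutant coordinates in component space.
    """

    rotation: pd.DataFrame  # index = input columns, columns = PC1..PCm
    explained_variance: np.ndarray
    scores: pd.DataFrame  # rows = mutants, columns = PC1..PCm
    standardized: pd.DataFrame  # the centered/scaled input actually used
    dropped_columns: list[str]

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.explained_variance / self.explained_variance.sum()


def _encode_pca_columns(table: pd.DataFrame) -> pd.DataFrame:
    cols = {}
    for name in ("rsa", "wcn", "mean_score"):
        if name in table.columns and table[name].notna().all():
            cols[name] = table[name].to_numpy(dtype=float)
    if "ss" in table.columns:
        for level in ("helix", "loop", "sheet"):
            cols[f"ss_{level}"] = (table["ss"] == level).to_numpy(dtype=float)
    return pd.DataFrame(cols)


def pca_predictors(table: pd.DataFrame) -> PCAResult:
    """PCA of the predictor columns (RSA, WCN, mean score, SS indicators).

    Every column is centered and scaled to unit sample variance, so the
    decomposition is of the correlation matrix: heterogeneous units (0-1
    RSA, 1/A^2 WCN, large-magnitude design scores) contribute equally.
    Zero-variance columns are dropped with a log entry.  Component sign is
    fixed so the largest-magnitude loading of each axis is positive.
    """
    data = _encode_pca_columns(table)
    if data.shape[1] == 0:
        raise EncodingError("no complete predictor columns available for PCA")
    if len(data) < 3:
        raise ValueError("PCA needs at least 3 rows")
    sd = data.std(ddof=1)
    dropped = [c for c in data.columns if sd[c] == 0 or not np.isfinite(sd[c])]
    if dropped:
        logger.warning("dropping zero-variance columns from PCA: %s", dropped)
        data = data.drop(columns=dropped)
        sd = sd.drop(index=dropped)
    Z = (data - data.mean()) / sd
    corr = np.asarray(Z.T @ Z) / (len(Z) - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # deterministic sign: largest-|loading| entry of each axis positive
    for j in range(eigvecs.shape[1]):
        i = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[i, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    pc_names = [f"PC{j + 1}" for j in range(eigvecs.shape[1])]
    rotation = pd.DataFrame(eigvecs, index=data.columns, columns=pc_names)
    scores = pd.DataFrame(
        Z.to_numpy() @ eigvecs, index=table.index, columns=pc_names
    )
    return PCAResult(
        rotation=rotation,
        explained_variance=eigvals,
        scores=scores,
        standardized=Z,
        dropped_columns=dropped,
    )


def group_stats_report(table: pd.DataFrame) -> dict:
    """Per-predictor Welch t-tests plus the SS chi-squared test, as a dict.

    The structure mirrors the standard group-comparison figure: one t-test
    per continuous predictor and one contingency test for secondary
    structure.
    """
    labels = table["functional"].to_numpy(dtype=bool)
    report: dict = {"t_tests": {}, "n_tolerated": int(labels.sum()),
                    "n_non_tolerated": int((~labels).sum())}
    for name in ("rsa", "wcn", "mean_score"):
        if name not in table.columns or table[name].isna().any():
            continue
        tt = group_t_test(table[name], labels)
        report["t_tests"][name] = {
            "t": tt.statistic,
            "p": tt.pvalue,
            "mean_tolerated": tt.mean_tolerated,
            "mean_non_tolerated": tt.mean_non_tolerated,
        }
    ct = ss_contingency(table)
    stat, dof, p = chi_square_test(ct)
    report["ss_contingency"] = {
        "counts": ct.counts.to_dict(),
        "tolerated_fractions": {
            k: (None if pd.isna(v) else float(v))
            for k, v in ct.tolerated_fractions.items()
        },
        "chi2": stat,
        "dof": dof,
        "p": p,
    }
    return report
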