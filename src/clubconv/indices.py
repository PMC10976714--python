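"""Composite indices by correlation screening and first-PC extraction.

The composite (e.g. a governance-quality or ICT-access index) is the
first principal component of the indicator correlation matrix, with the
eigenvalue table and loadings reported alongside; indicators with
|loading| > 0.4 on component 1 are flagged as important contributors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

LOADING_FLAG_THRESHOLD = 0.4
_PSD_TOL = 1e-8


@dataclass(frozen=True)
class CompositeIndex:
    indicators: tuple[str, ...]
    correlation: pd.DataFrame
    eigenvalues: np.ndarray          # descending
    proportions: np.ndarray
    cumulative: np.ndarray
    loadings: pd.DataFrame           # indicators x components, unit-norm columns
    scores: pd.Series | None         # component-1 scores (None if built from a matrix)
    important: tuple[str, ...]       # |comp-1 loading| > 0.4
    rescaling: str = "none"

    def eigen_table(self) -> pd.DataFrame:
        """Eigenvalue / difference / proportion / cumulative table."""
        diff = np.append(-np.diff(self.eigenvalues), np.nan)
        return pd.DataFrame(
            {
                "eigenvalue": self.eigenvalues,
                "difference": diff,
                "proportion": self.proportions,
                "cumulative": self.cumulative,
            },
            index=[f"Comp {k + 1}" for k in range(len(self.eigenvalues))],
        )


def correlation_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlations with pairwise p-values on casewise-complete rows.

    Returns (correlations, p-values); a constant column is an error since
    its correlations are undefined.
    """
    table = pd.DataFrame(table)
    if table.shape[1] < 2:
        raise ValueError("need at least 2 indicator columns")
    complete = table.dropna()
    if len(complete) < 3:
        raise ValueError("need at least 3 complete observations")
    constant = [c for c in complete.columns if complete[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant columns have undefined correlation: {constant}")
    cols = list(complete.columns)
    k = len(cols)
    corr = np.eye(k)
    pval = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            r, p = stats.pearsonr(complete[cols[i]], complete[cols[j]])
            corr[i, j] = corr[j, i] = r
            pval[i, j] = pval[j, i] = p
    return (pd.DataFrame(corr, index=cols, columns=cols),
            pd.DataFrame(pval, index=cols, columns=cols))


def pca_index(data, rescaling: str = "none") -> CompositeIndex:
    """Principal-component composite from an indicator table or a
    correlation matrix.

    With a table, Pearson correlations are computed on casewise-complete
    rows and component-1 scores are produced from the standardized
    indicators.  Components are sorted by eigenvalue descending, and each
    eigenvector's sign is fixed so the first indicator loads >= 0.
    """
    scores = None
    if isinstance(data, pd.DataFrame) and _is_correlation(data):
        corr = data.astype(float)
        table = None
    elif isinstance(data, np.ndarray) and data.ndim == 2 and _is_correlation(pd.DataFrame(data)):
        corr = pd.DataFrame(
            data.astype(float),
            index=[f"x{i + 1}" for i in range(data.shape[0])],
            columns=[f"x{i + 1}" for i in range(data.shape[0])],
        )
        table = None
    else:
        table = pd.DataFrame(data).dropna()
        corr, _ = correlation_matrix(table)
    names = tuple(corr.columns)
    C = corr.to_numpy()
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("correlation matrix is not symmetric")
    eigval, eigvec = np.linalg.eigh(C)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if eigval[-1] < -_PSD_TOL * max(1.0, abs(eigval[0])):
        raise ValueError(
            f"matrix is not positive semi-definite (min eigenvalue {eigval[-1]:.3g})"
        )
    eigval = np.clip(eigval, 0.0, None)
    # sign convention: first nonzero loading of each component >= 0
    for k in range(eigvec.shape[1]):
        lead = np.flatnonzero(np.abs(eigvec[:, k]) > 1e-12)
        if lead.size and eigvec[lead[0], k] < 0:
            eigvec[:, k] = -eigvec[:, k]
    total = eigval.sum()
    proportions = eigval / total
    loadings = pd.DataFrame(
        eigvec, index=names,
        columns=[f"Comp {k + 1}" for k in range(len(names))],
    )
    if table is not None:
        z = (table - table.mean()) / table.std(ddof=1)
        raw_scores = pd.Series(z.to_numpy() @ eigvec[:, 0], index=table.index,
                               name="score")
        scores = rescale_index(raw_scores, rescaling)
    important = tuple(
        n for n, v in zip(names, eigvec[:, 0])
        if abs(v) > LOADING_FLAG_THRESHOLD
    )
    return CompositeIndex(
        indicators=names,
        correlation=corr,
        eigenvalues=eigval,
        proportions=proportions,
        cumulative=np.cumsum(proportions),
        loadings=loadings,
        scores=scores,
        important=important,
        rescaling=rescaling,
    )


def rescale_index(scores, mode: str = "none"):
    """Affine rescaling of index scores; order is always preserved.

    ``shift_min_to_zero`` anchors the minimum at 0 (the convention behind
    0-based composite scales); ``none`` returns the input unchanged.
    """
    scores = pd.Series(scores)
    if mode == "none":
        return scores
    if mode == "shift_min_to_zero":
        return scores - scores.min()
    raise ValueError(f"unknown rescaling mode {mode!r}")


def _is_correlation(df: pd.DataFrame) -> bool:
    if df.shape[0] != df.shape[1]:
        return False
    a = df.to_numpy(dtype=float)
    return (np.allclose(np.diag(a), 1.0, atol=1e-8)
            and np.allclose(a, a.T, atol=1e-8)
            and np.nanmax(np.abs(a)) <= 1.0 + 1e-8)
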