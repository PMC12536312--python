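"""Covariance-homogeneity testing (Box's M) and FDR control (Benjamini–Hochberg).

Box's M compares the pooled within-group covariance against the per-group
covariances,

    M = (N - k) ln|S_pooled| - sum_j (n_j - 1) ln|S_j| ,

and refers ``M * c`` to a chi-square with ``(k-1) p (p+1) / 2`` degrees of
freedom, where the small-sample correction is

    c = 1 - (2p² + 3p - 1) / (6 (p+1) (k-1)) * (sum_j 1/(n_j-1) - 1/(N-k)).

Covariances use the n-1 denominator so the (n_j - 1) weights are consistent.
The chi-square (not F) approximation is implemented.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["GroupCovariances", "BoxMResult", "AdjustedPValues",
           "boxs_m_test", "benjamini_hochberg", "group_covariances_from_tidy"]


@dataclass(frozen=True)
class GroupCovariances:
    """Per-group sample sizes and p x p sample covariance matrices."""

    labels: tuple[str, ...]
    n: tuple[int, ...]
    S: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        p = self.S[0].shape[0]
        for lab, nj, Sj in zip(self.labels, self.n, self.S):
            if Sj.shape != (p, p) or not np.allclose(Sj, Sj.T, atol=1e-10):
                raise ValueError(f"group {lab!r}: covariance not symmetric {p}x{p}")
            if nj <= p:
                raise ValueError(
                    f"group {lab!r}: sample size {nj} must exceed the number "
                    f"of traits {p}"
                )

    @property
    def p(self) -> int:
        return self.S[0].shape[0]

    @property
    def k(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class BoxMResult:
    M: float
    correction: float  # c
    statistic: float  # chi-square value, M * c
    df: int
    p_value: float


@dataclass(frozen=True)
class AdjustedPValues:
    raw: tuple[float, ...]
    adjusted: tuple[float, ...]
    method: str = "BH"


def _as_group_covariances(
    data: GroupCovariances | Mapping[str, np.ndarray] | pd.DataFrame,
    group_col: str = "group",
) -> GroupCovariances:
    if isinstance(data, GroupCovariances):
        return data
    if isinstance(data, pd.DataFrame):
        groups = {
            str(g): grp.drop(columns=[group_col]).to_numpy(dtype=float)
            for g, grp in data.groupby(group_col, observed=True)
        }
    else:
        groups = {str(g): np.asarray(x, dtype=float) for g, x in data.items()}
    labels, ns, covs = [], [], []
    for lab in groups:
        x = groups[lab]
        if x.ndim != 2:
            raise ValueError(f"group {lab!r}: samples must be 2-D (n x p)")
        labels.append(lab)
        ns.append(x.shape[0])
        covs.append(np.cov(x, rowvar=False, ddof=1))
    p = covs[0].shape[0]
    if any(c.shape != (p, p) for c in covs):
        raise ValueError("groups have mismatched trait sets")
    return GroupCovariances(tuple(labels), tuple(ns), tuple(covs))


def _logdet(S: np.ndarray, label: str) -> float:
    sign, ld = np.linalg.slogdet(S)
    if sign <= 0 or not np.isfinite(ld):
        raise ValueError(f"group {label!r}: singular covariance matrix")
    return float(ld)


def boxs_m_test(
    data: GroupCovariances | Mapping[str, np.ndarray] | pd.DataFrame,
    group_col: str = "group",
) -> BoxMResult:
    """Box's M homogeneity test with the chi-square approximation.

    ``data`` may be per-group multivariate samples (mapping of label to
    (n x p) arrays, or a wide DataFrame with a group column) or precomputed
    :class:`GroupCovariances`.
    """
    gc = _as_group_covariances(data, group_col)
    if gc.k < 2:
        raise ValueError("need at least 2 groups")
    p, k = gc.p, gc.k
    n = np.asarray(gc.n, dtype=float)
    N = n.sum()
    weights = n - 1.0
    S_pooled = sum(w * S for w, S in zip(weights, gc.S)) / (N - k)
    M = (N - k) * _logdet(S_pooled, "pooled") - sum(
        w * _logdet(S, lab) for w, S, lab in zip(weights, gc.S, gc.labels)
    )
    c = 1.0 - (2.0 * p**2 + 3.0 * p - 1.0) / (6.0 * (p + 1.0) * (k - 1.0)) * (
        np.sum(1.0 / weights) - 1.0 / (N - k)
    )
    statistic = M * c
    df = (k - 1) * p * (p + 1) // 2
    p_value = float(stats.chi2.sf(statistic, df))
    return BoxMResult(
        M=float(M), correction=float(c), statistic=float(statistic),
        df=int(df), p_value=p_value,
    )


def group_covariances_from_tidy(
    df: pd.DataFrame,
    group_cols: Sequence[str] = ("line", "replicate"),
    trait_col: str = "trait",
    value_col: str = "value",
    id_col: str = "individual",
) -> GroupCovariances:
    """Pivot a tidy (individual, group, trait, value) table into GroupCovariances."""
    wide = df.pivot_table(
        index=[*group_cols, id_col], columns=trait_col, values=value_col
    ).reset_index()
    labels, ns, covs = [], [], []
    traits = [c for c in wide.columns if c not in (*group_cols, id_col)]
    for key, grp in wide.groupby(list(group_cols), observed=True):
        label = "_".join(str(x) for x in (key if isinstance(key, tuple) else (key,)))
        x = grp[traits].to_numpy(dtype=float)
        labels.append(label)
        ns.append(x.shape[0])
        covs.append(np.cov(x, rowvar=False, ddof=1))
    return GroupCovariances(tuple(labels), tuple(ns), tuple(covs))


def benjamini_hochberg(raw: Sequence[float]) -> AdjustedPValues:
    """Benjamini–Hochberg step-up adjustment, preserving input order."""
    arr = np.asarray(list(raw), dtype=float)
    if arr.size == 0:
        raise ValueError("empty p-value list")
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(arr, method="fdr_bh")
    return AdjustedPValues(raw=tuple(arr), adjusted=tuple(adjusted))
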