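"""Expression-level operations: per-million normalization, expression-level
binning, t-test / ANOVA differential expression and the 2^-ddCt utility.

The t-test is the classical two-sided Student's t with pooled variance.
Degenerate zero-variance cases follow explicit conventions so that fully
deterministic (acceptance-mode) counts give exact calls: when both groups
have zero variance, p = 1 for equal means and p = 0 for unequal means.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

log = logging.getLogger(__name__)

NORM_TOTAL = 1e6
LOW_THRESHOLD = 10.0


def normalize(raw: pd.DataFrame) -> pd.DataFrame:
    """Scale every library (column) to sum to 1e6 (abundance per million
    miRNA-mapped molecules). All-zero columns pass through with a warning."""
    if (raw.to_numpy() < 0).any():
        raise InputError("count matrix contains negative values")
    totals = raw.sum(axis=0)
    zero = totals == 0
    if zero.any():
        log.warning("libraries with zero total passed through: %s",
                    list(totals.index[zero]))
    scale = np.where(zero, 0.0, NORM_TOTAL / totals.replace(0, np.nan))
    return raw * scale


def bin_expression(mean_abundance: float, dataset_mean: float) -> str:
    """Three-level expression bin: low (<=10), medium (10 < x <= dataset mean),
    high (> dataset mean)."""
    if mean_abundance < 0:
        raise InputError("abundance must be non-negative")
    if dataset_mean <= LOW_THRESHOLD:
        warnings.warn("dataset mean <= 10; medium bin is empty", stacklevel=2)
    if mean_abundance > dataset_mean:
        return "high"
    if mean_abundance > LOW_THRESHOLD:
        return "medium"
    return "low"


def _pooled_t_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized two-sided pooled-variance t-test across rows, with the
    zero-variance degenerate conventions."""
    n1, n2 = a.shape[1], b.shape[1]
    m1 = a.mean(axis=1)
    m2 = b.mean(axis=1)
    v1 = a.var(axis=1, ddof=1)
    v2 = b.var(axis=1, ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m2 - m1) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        p = 2 * stats.t.sf(np.abs(t), df)
    degenerate = (v1 == 0) & (v2 == 0)
    p = np.where(degenerate & (m1 == m2), 1.0, p)
    p = np.where(degenerate & (m1 != m2), 0.0, p)
    return p


def de_pairwise(
    matrix: pd.DataFrame,
    a_libs: list[str],
    b_libs: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-miRNA two-sample comparison of group B against reference group A.

    Returns a table with mean_A, mean_B, log2fc (pseudocount +1), p, direction
    (up iff mean_B > mean_A strictly) and a significance flag at ``alpha``.
    """
    if len(a_libs) < 2 or len(b_libs) < 2:
        raise InputError("need at least two replicates per group")
    a = matrix[a_libs].to_numpy(dtype=float)
    b = matrix[b_libs].to_numpy(dtype=float)
    p = _pooled_t_p(a, b)
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    direction = np.where(m2 > m1, "up", np.where(m2 < m1, "down", "flat"))
    out = pd.DataFrame(
        {
            "mean_A": m1,
            "mean_B": m2,
            "log2fc": np.log2((m2 + 1) / (m1 + 1)),
            "p": p,
            "direction": direction,
            "significant": p < alpha,
        },
        index=matrix.index,
    )
    return out


def de_multigroup(matrix: pd.DataFrame, groups: list[list[str]]) -> pd.Series:
    """Per-miRNA one-way ANOVA p-value across >=2 groups, with the same
    zero-variance degenerate conventions as the pairwise test."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise InputError("need >=2 groups with >=2 replicates each")
    arrays = [matrix[g].to_numpy(dtype=float) for g in groups]
    within_flat = np.all(
        np.stack([arr.var(axis=1) == 0 for arr in arrays]), axis=0
    )
    means = np.stack([arr.mean(axis=1) for arr in arrays])
    equal_means = np.all(means == means[0], axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        _f, p = stats.f_oneway(*arrays, axis=1)
    p = np.where(within_flat & equal_means, 1.0, p)
    p = np.where(within_flat & ~equal_means, 0.0, p)
    return pd.Series(p, index=matrix.index, name="p")


def ddct(
    ct_target_treat: float,
    ct_ref_treat: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative qPCR quantification: 2^-((Ct_t,T - Ct_r,T) - (Ct_t,C - Ct_r,C))."""
    ddct_val = (ct_target_treat - ct_ref_treat) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct_val))
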