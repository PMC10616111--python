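"""Differential translation between two conditions on per-ORF Ribo counts.

A self-contained two-group test on a count matrix: median-of-ratios size
factors, a pooled method-of-moments common negative-binomial dispersion, an
exact-style conditional test on normalized pseudo-counts (the group sums of
NB counts are conditioned on their total, giving a negative-hypergeometric
null; two-sided p by summing all outcomes no more probable than the
observed one), and Benjamini–Hochberg FDR control.  The screen applies the
fold-change/FDR rule (FC >= 2, FDR < 0.05) to its output.

Log2 fold changes are condition 2 over condition 1, computed on normalized
group means with a pseudocount of 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

DISPERSION_FLOOR = 1e-4
DEFAULT_PRIOR_DISPERSION = 0.1
LOG2FC_PSEUDOCOUNT = 0.5


def size_factors(counts: pd.DataFrame) -> np.ndarray:
    """Median-of-ratios size factors (one per column/library).

    Computed over ORFs with nonzero counts in every library; factors are
    rescaled to geometric mean 1.  When no ORF is nonzero everywhere, falls
    back to library-total scaling with a warning.
    """
    mat = counts.to_numpy(dtype=float)
    nonzero = (mat > 0).all(axis=1)
    if nonzero.sum() == 0:
        warnings.warn(
            "no ORF with nonzero counts in all libraries; "
            "falling back to library-total size factors",
            stacklevel=2,
        )
        totals = mat.sum(axis=0)
        if (totals == 0).any():
            raise ValueError("library with zero total counts")
        sf = totals.astype(float)
    else:
        sub = mat[nonzero]
        loggeo = np.mean(np.log(sub), axis=1, keepdims=True)
        sf = np.median(sub / np.exp(loggeo), axis=0)
    sf = sf / np.exp(np.mean(np.log(sf)))
    return sf


def estimate_dispersion(
    counts: np.ndarray,
    groups: Sequence[int],
    sf: Optional[np.ndarray] = None,
    prior: float = DEFAULT_PRIOR_DISPERSION,
) -> float:
    """Pooled method-of-moments common NB dispersion on normalized counts.

    Solves ``sum (n_g-1)(s2_g - m_g) = phi * sum (n_g-1) m_g^2`` over all
    ORFs and groups, floored at 1e-4.  With a single replicate per group the
    configured prior dispersion is returned.
    """
    counts = np.asarray(counts, dtype=float)
    groups = np.asarray(groups)
    if sf is None:
        sf = np.ones(counts.shape[1])
    y = counts / sf
    num = 0.0
    den = 0.0
    any_reps = False
    for g in np.unique(groups):
        yg = y[:, groups == g]
        n = yg.shape[1]
        if n < 2:
            continue
        any_reps = True
        m = yg.mean(axis=1)
        s2 = yg.var(axis=1, ddof=1)
        num += float(((n - 1) * (s2 - m)).sum())
        den += float(((n - 1) * m**2).sum())
    if not any_reps or den == 0:
        return prior
    return max(num / den, DISPERSION_FLOOR)


def _exact_nb_pvalue(s1: int, s2: int, r1: float, r2: float) -> float:
    """Two-sided conditional NB test: P over splits of s1+s2 no more likely
    than the observed split, under group NB totals with sizes r1, r2."""
    s = s1 + s2
    if s == 0:
        return 1.0
    k = np.arange(s + 1)
    logp = (
        gammaln(k + r1)
        - gammaln(k + 1)
        + gammaln(s - k + r2)
        - gammaln(s - k + 1)
    )
    logp -= logsumexp(logp)
    p_obs = logp[s1]
    return float(np.exp(logsumexp(logp[logp <= p_obs + 1e-10])))


def nb_test(
    counts_group1: np.ndarray,
    counts_group2: np.ndarray,
    sf1: Optional[np.ndarray] = None,
    sf2: Optional[np.ndarray] = None,
    dispersion: Optional[float] = None,
    prior_dispersion: float = DEFAULT_PRIOR_DISPERSION,
) -> pd.DataFrame:
    """Per-ORF two-group NB exact-style test.

    ``counts_group*`` are (n_orfs, n_reps) matrices; size factors default to
    1.  Returns a DataFrame with ``log2fc`` (group 2 vs 1, pseudocount 0.5
    on normalized means), ``pvalue``, and an ``all_zero`` flag (such ORFs
    get p=1, log2fc=0).
    """
    c1 = np.atleast_2d(np.asarray(counts_group1, dtype=float))
    c2 = np.atleast_2d(np.asarray(counts_group2, dtype=float))
    n1, n2 = c1.shape[1], c2.shape[1]
    if n1 < 1 or n2 < 1:
        raise ValueError("each group needs at least one replicate")
    if sf1 is None:
        sf1 = np.ones(n1)
    if sf2 is None:
        sf2 = np.ones(n2)
    y1 = c1 / np.asarray(sf1)
    y2 = c2 / np.asarray(sf2)
    if dispersion is None:
        counts = np.hstack([c1, c2])
        sf = np.concatenate([sf1, sf2])
        groups = np.array([0] * n1 + [1] * n2)
        dispersion = estimate_dispersion(counts, groups, sf, prior=prior_dispersion)
    phi = max(dispersion, DISPERSION_FLOOR)
    r1, r2 = n1 / phi, n2 / phi

    m1 = y1.mean(axis=1)
    m2 = y2.mean(axis=1)
    log2fc = np.log2((m2 + LOG2FC_PSEUDOCOUNT) / (m1 + LOG2FC_PSEUDOCOUNT))
    s1 = np.rint(y1.sum(axis=1)).astype(int)
    s2 = np.rint(y2.sum(axis=1)).astype(int)
    all_zero = (s1 == 0) & (s2 == 0)
    pvals = np.ones(len(s1))
    for i in range(len(s1)):
        if all_zero[i]:
            continue
        pvals[i] = min(1.0, _exact_nb_pvalue(int(s1[i]), int(s2[i]), r1, r2))
    log2fc = np.where(all_zero, 0.0, log2fc)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": pvals,
            "all_zero": all_zero,
            "mean_norm_group1": m1,
            "mean_norm_group2": m2,
            "dispersion": phi,
        }
    )


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_translation(
    count_matrix: pd.DataFrame,
    libraries: pd.DataFrame,
    condition1: str,
    condition2: str,
    dispersion: Optional[float] = None,
    prior_dispersion: float = DEFAULT_PRIOR_DISPERSION,
) -> pd.DataFrame:
    """Full two-condition differential-translation table for a count matrix.

    ``count_matrix`` is orf_id x library_id (Ribo counts); ``libraries``
    holds columns library_id / condition.  Size factors are estimated across
    all listed libraries jointly; FDR is BH over all tested ORFs.
    """
    libs1 = libraries.loc[libraries["condition"] == condition1, "library_id"].tolist()
    libs2 = libraries.loc[libraries["condition"] == condition2, "library_id"].tolist()
    if not libs1 or not libs2:
        raise ValueError(f"no libraries for conditions {condition1!r}/{condition2!r}")
    mat = count_matrix[libs1 + libs2]
    sf = size_factors(mat)
    sf1, sf2 = sf[: len(libs1)], sf[len(libs1) :]
    res = nb_test(
        count_matrix[libs1].to_numpy(),
        count_matrix[libs2].to_numpy(),
        sf1,
        sf2,
        dispersion=dispersion,
        prior_dispersion=prior_dispersion,
    )
    res.insert(0, "orf_id", count_matrix.index.to_numpy())
    res["fdr"] = bh_fdr(res["pvalue"].to_numpy())
    return res
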