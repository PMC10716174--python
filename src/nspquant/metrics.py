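"""Benchmark quality metrics for protein-level SILAC ratio matrices.

These are the summary statistics used to compare acquisition methods and
mixture designs: how many protein groups are quantified, how precise the
replicate ratios are (CV%), how far the ratios sit from the theoretical
mixing ratio, how many cells are missing, how strongly labeled material
is enriched over unlabeled background, and how samples separate in a PCA
of their log2 ratio profiles.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "cv_percent",
    "replicate_cv",
    "accuracy_deviation",
    "count_quantified",
    "missing_rate",
    "pca_ratios",
    "enrichment_fold",
]


def cv_percent(values, min_n: int = 2) -> float:
    """Coefficient of variation, 100 * sample SD / mean, of linear-scale
    replicate ratios.  NaN when fewer than ``min_n`` values are present
    or the mean is zero."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < min_n:
        return np.nan
    m = v.mean()
    if m == 0:
        log.warning("CV undefined for zero-mean values")
        return np.nan
    return 100.0 * v.std(ddof=1) / m


def replicate_cv(ratios: pd.DataFrame, groups: dict | None = None, log_scale_input: bool = True) -> pd.DataFrame:
    """Per-protein CV% across replicate columns of a ratio matrix.

    ``ratios`` is protein x sample; CVs are computed on linear-scale
    ratios (``2**x`` when the matrix holds log2 values, the default).
    ``groups`` maps each sample column to a condition label; replicates
    of the same condition are pooled.  Without it, all columns are one
    condition named "all".
    """
    lin = 2.0**ratios if log_scale_input else ratios
    if groups is None:
        groups = {c: "all" for c in ratios.columns}
    out = {}
    for cond in sorted(set(groups.values())):
        cols = [c for c in ratios.columns if groups.get(c) == cond]
        out[cond] = lin[cols].apply(lambda row: cv_percent(row.to_numpy()), axis=1)
    return pd.DataFrame(out)


def accuracy_deviation(ratios: pd.DataFrame, theoretical_log2: float):
    """Per-protein deviation of the median-over-samples log2 ratio from
    the theoretical log2 mixing ratio, plus the summary median.

    Returns ``(deviations: Series, median: float)``.
    """
    dev = ratios.median(axis=1, skipna=True) - theoretical_log2
    dev = dev.dropna()
    return dev, (float(dev.median()) if len(dev) else np.nan)


def count_quantified(ratios: pd.DataFrame, scope: str = "overall"):
    """Number of protein groups with at least one present ratio.

    ``scope="overall"`` returns a single count (union over samples);
    ``scope="per_sample"`` returns a per-column Series.
    """
    if scope == "overall":
        return int(ratios.notna().any(axis=1).sum())
    if scope == "per_sample":
        return ratios.notna().sum(axis=0)
    raise ValueError(f"scope must be 'overall' or 'per_sample', got {scope!r}")


def missing_rate(ratios: pd.DataFrame, scope: str = "overall"):
    """Percentage of absent cells among proteins quantified in >= 1 sample."""
    sub = ratios.loc[ratios.notna().any(axis=1)]
    if sub.size == 0:
        return np.nan
    if scope == "overall":
        return 100.0 * float(sub.isna().sum().sum()) / sub.size
    if scope == "per_sample":
        return 100.0 * sub.isna().mean(axis=0)
    raise ValueError(f"scope must be 'overall' or 'per_sample', got {scope!r}")


def pca_ratios(ratios: pd.DataFrame):
    """PCA of samples on their complete-case log2 ratio profiles.

    Proteins with any absent value are dropped; the sample x protein
    matrix is column-centered and decomposed by SVD.  Returns
    ``(scores, explained)``: per-sample scores on the principal
    components and explained-variance fractions (summing to 1).
    """
    complete = ratios.dropna(axis=0, how="any")
    if ratios.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    if len(complete) < 2:
        raise ValueError(f"only {len(complete)} complete-case protein(s); PCA needs >= 2")
    X = complete.to_numpy(float).T  # samples x proteins
    X = X - X.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    k = min(X.shape)
    scores = pd.DataFrame(
        U[:, :k] * s[:k],
        index=ratios.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    var = s[:k] ** 2
    explained = pd.Series(var / var.sum(), index=scores.columns)
    return scores, explained


def enrichment_fold(enriched, non_enriched) -> float:
    """Fold enrichment: median(enriched) / median(non-enriched), on the
    linear scale of labeled/unlabeled intensity ratios."""
    a = np.asarray(enriched, dtype=float)
    b = np.asarray(non_enriched, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both distributions must be non-empty")
    mb = np.median(b)
    if mb == 0:
        log.warning("non-enriched median is zero; fold enrichment undefined")
        return np.nan
    return float(np.median(a) / mb)
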