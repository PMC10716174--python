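"""Selection and early/intermediate/late classification of regulated
proteins across a treatment time course.

A protein is selected when it shows a strong, significant change at any
time point (|log2 FC| > 1 and BH-adjusted p < 0.05) and its replicate
ratios are reproducible (CV < 20%).  Selected proteins are assigned a
response class from the earliest time point at which a relaxed
significance rule holds (|log2 FC| > 0.585 and adjusted p < 0.05):
2 h -> early, 4-9 h -> intermediate, 24 h -> late by default.

The CV gate is computed on linear-scale ratios; by default it is the
maximum over time points of the within-time-point replicate CV, so a
genuinely regulated protein (whose ratio steps between time points) is
not penalized for its own regulation.  A pooled-across-time variant is
available via ``cv_mode="pooled"``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .metrics import cv_percent

log = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_CLASS_MAP",
    "cv_across_time",
    "select_candidates",
    "classify_response",
    "timecourse_report",
]

DEFAULT_CLASS_MAP = {
    "2h": "early",
    "4h": "intermediate",
    "6h": "intermediate",
    "9h": "intermediate",
    "24h": "late",
}

_CLASS_ORDER = {"early": 0, "intermediate": 1, "late": 2, "none": 3}


def _check_time_points(de_by_tp: dict, time_points) -> None:
    missing = [tp for tp in time_points if tp not in de_by_tp]
    if missing:
        raise ValueError(
            f"missing DE results for time point(s) {missing}; expected {list(time_points)}, "
            f"found {sorted(de_by_tp)}"
        )


def cv_across_time(ratios_by_tp: dict, mode: str = "max") -> pd.Series:
    """CV% of a protein's linear-scale ratios over the time course.

    ``ratios_by_tp`` maps time point -> protein x replicate log2 ratio
    frame.  ``mode="max"``: the largest within-time-point replicate CV;
    ``mode="pooled"``: one CV over all replicates of all time points.
    """
    if mode not in {"max", "pooled"}:
        raise ValueError(f"cv mode must be 'max' or 'pooled', got {mode!r}")
    linear = {tp: 2.0**df for tp, df in ratios_by_tp.items()}
    proteins = sorted(set().union(*[df.index for df in linear.values()]))
    if mode == "pooled":
        pooled = pd.concat([df.reindex(proteins) for df in linear.values()], axis=1)
        return pooled.apply(lambda r: cv_percent(r.to_numpy()), axis=1)
    per_tp = pd.DataFrame(
        {tp: df.reindex(proteins).apply(lambda r: cv_percent(r.to_numpy()), axis=1)
         for tp, df in linear.items()}
    )
    return per_tp.max(axis=1, skipna=True)


def select_candidates(
    de_by_tp: dict,
    ratios_by_tp: dict,
    time_points,
    fc_threshold: float = 1.0,
    alpha: float = 0.05,
    cv_threshold: float = 20.0,
    cv_mode: str = "max",
) -> pd.DataFrame:
    """Select robustly regulated proteins across the time course.

    ``de_by_tp`` maps time point -> DE result frame (index protein,
    columns log2_fc and p_adj); ``ratios_by_tp`` the matching replicate
    ratio matrices for the CV gate.  Returns a frame indexed by protein
    with columns ``cv_across_time``, ``hit_any`` and ``selected``.
    """
    _check_time_points(de_by_tp, time_points)
    cv = cv_across_time(ratios_by_tp, mode=cv_mode)
    proteins = cv.index
    hit = pd.Series(False, index=proteins)
    for tp in time_points:
        de = de_by_tp[tp].reindex(proteins)
        # untested time points count as non-significant, not as errors
        h = (de["log2_fc"].abs() > fc_threshold) & (de["p_adj"] < alpha)
        hit |= h.fillna(False)
    out = pd.DataFrame({"cv_across_time": cv, "hit_any": hit})
    out["selected"] = hit & (cv < cv_threshold)
    return out


def classify_response(
    protein: str,
    de_by_tp: dict,
    time_points,
    class_map: dict | None = None,
    fc_threshold: float = 0.585,
    alpha: float = 0.05,
):
    """Earliest-significance response class for one selected protein.

    Returns ``(class, earliest time point)``; class "none" (with a
    warning) if no time point passes the relaxed rule, which cannot
    happen when the protein was selected with consistent thresholds.
    """
    class_map = class_map or DEFAULT_CLASS_MAP
    for tp in time_points:
        de = de_by_tp[tp]
        if protein not in de.index:
            continue
        row = de.loc[protein]
        if abs(row["log2_fc"]) > fc_threshold and row["p_adj"] < alpha:
            return class_map.get(tp, "none"), tp
    log.warning("selected protein %s passes no time point at the relaxed rule", protein)
    return "none", None


def timecourse_report(
    de_by_tp: dict,
    ratios_by_tp: dict,
    time_points,
    class_map: dict | None = None,
    select_fc: float = 1.0,
    class_fc: float = 0.585,
    alpha: float = 0.05,
    cv_threshold: float = 20.0,
    cv_mode: str = "max",
    genes: pd.Series | None = None,
) -> pd.DataFrame:
    """Heatmap-ready table of selected proteins.

    One row per selected protein: response class, earliest significant
    time point, CV across time, and per-time-point log2 FC with a
    significance flag (relaxed rule).  Sorted by class, then earliest
    significance, then protein.
    """
    _check_time_points(de_by_tp, time_points)
    sel = select_candidates(
        de_by_tp, ratios_by_tp, time_points,
        fc_threshold=select_fc, alpha=alpha,
        cv_threshold=cv_threshold, cv_mode=cv_mode,
    )
    chosen = sel.index[sel["selected"]]
    rows = []
    for prot in chosen:
        cls, earliest = classify_response(
            prot, de_by_tp, time_points, class_map, fc_threshold=class_fc, alpha=alpha
        )
        rec = {
            "protein_group": prot,
            "gene": genes.get(prot) if genes is not None else None,
            "response_class": cls,
            "earliest_sig_timepoint": earliest,
            "cv_across_time": sel.loc[prot, "cv_across_time"],
        }
        for tp in time_points:
            de = de_by_tp[tp]
            if prot in de.index:
                fc = de.loc[prot, "log2_fc"]
                sig = bool(abs(fc) > class_fc and de.loc[prot, "p_adj"] < alpha)
            else:
                fc, sig = np.nan, False
            rec[f"log2_fc_{tp}"] = fc
            rec[f"significant_{tp}"] = sig
        rows.append(rec)
    cols = ["protein_group", "gene", "response_class", "earliest_sig_timepoint", "cv_across_time"]
    cols += [f"log2_fc_{tp}" for tp in time_points] + [f"significant_{tp}" for tp in time_points]
    out = pd.DataFrame(rows, columns=cols)
    tp_order = {tp: i for i, tp in enumerate(time_points)}
    out = out.sort_values(
        by=["response_class", "earliest_sig_timepoint", "protein_group"],
        key=lambda s: (
            s.map(_CLASS_ORDER) if s.name == "response_class"
            else s.map(tp_order) if s.name == "earliest_sig_timepoint"
            else s
        ),
    ).reset_index(drop=True)
    return out
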