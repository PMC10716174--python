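"""Hypergeometric over-representation analysis against gene sets.

Given a query of significant proteins and the quantified proteins as
background, each gene set is first restricted to the background; the
one-sided hypergeometric tail P(X >= k) is evaluated in log space for
numerical stability, and Benjamini-Hochberg correction is applied across
the tested sets.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .diffexpr import adjust_bh

log = logging.getLogger(__name__)

__all__ = ["read_gmt", "write_gmt", "hypergeom_tail", "run_ora"]


def read_gmt(path) -> dict:
    """Read a GMT file: set name <tab> description <tab> genes...

    Returns ``{set name: frozenset of upper-cased gene symbols}``.
    """
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                if line.strip():
                    log.warning("skipping malformed GMT line %d", lineno)
                continue
            name = parts[0]
            if name in sets:
                raise ValueError(f"duplicate gene set name {name!r} at line {lineno}")
            genes = frozenset(g.strip().upper() for g in parts[2:] if g.strip())
            if genes:
                sets[name] = genes
    return sets


def write_gmt(sets: dict, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            fh.write("\t".join([name, description, *sorted(sets[name])]) + "\n")


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), in log space.

    N: background size, K: set size within background, n: query size,
    k: observed hits.  The sum runs over the attainable upper tail
    i = k .. min(n, K).
    """
    if not (0 <= k <= n <= N) or not (0 <= K <= N) or k > K:
        raise ValueError(f"inconsistent hypergeometric arguments k={k}, n={n}, K={K}, N={N}")
    if k <= 0:
        return 1.0
    hi = min(n, K)
    i = np.arange(k, hi + 1)
    log_terms = _log_binom(K, i) + _log_binom(N - K, n - i) - _log_binom(N, n)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def _first_symbol(g: str) -> str:
    return str(g).split(";")[0].strip().upper()


def run_ora(
    query,
    sets: dict,
    background,
    q_threshold: float = 0.05,
    min_set_size: int = 3,
) -> pd.DataFrame:
    """Over-representation of ``query`` genes in ``sets`` vs ``background``.

    Gene symbols are matched case-insensitively; for multi-gene groups
    the first symbol is used.  Query members outside the background are
    dropped with a warning.  Sets with fewer than ``min_set_size``
    members inside the background are skipped.  Returns one row per
    tested set with k, n, K, N, p, q, hits and a significance flag.
    """
    bg = {_first_symbol(g) for g in background}
    if not bg:
        raise ValueError("background is empty")
    q = {_first_symbol(g) for g in query}
    outside = q - bg
    if outside:
        log.warning("%d query gene(s) outside background dropped", len(outside))
        q &= bg

    rows = []
    for name in sorted(sets):
        members = {str(g).upper() for g in sets[name]} & bg
        if len(members) < min_set_size:
            continue
        hits = sorted(q & members)
        rows.append(
            {
                "set": name,
                "k": len(hits),
                "n": len(q),
                "K": len(members),
                "N": len(bg),
                "p": hypergeom_tail(len(hits), len(q), len(members), len(bg)),
                "hits": ";".join(hits),
            }
        )
    out = pd.DataFrame(rows, columns=["set", "k", "n", "K", "N", "p", "hits"])
    if len(out):
        out["q"] = adjust_bh(out["p"].to_numpy())
        out["significant"] = out["q"] < q_threshold
        out = out.sort_values(["p", "set"]).reset_index(drop=True)
    else:
        out["q"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out
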