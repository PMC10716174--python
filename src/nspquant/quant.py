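"""Protein-level SILAC channel quantification via MaxLFQ, and ratios.

MaxLFQ combines, for one protein, the pairwise median log2 peptide
ratios between quantification columns into a least-squares estimate of
per-column log2 abundance:

    min_x  sum over column pairs (a, b) sharing >= min_shared precursors
           of (x_b - x_a - median_k(log2 I_kb - log2 I_ka))^2

The solution is defined up to an additive constant per connected
component of the column-sharing graph; each component is anchored so
that the summed linear abundances equal the component's total observed
precursor intensity.  Columns sharing no precursor with any other column
fall back to their summed intensity.

Here the quantification columns are (run, channel) pairs, so the three
SILAC channels of each run are quantified like separate samples —
either jointly across all columns of a protein (default, keeps the
channels on one comparable scale) or per channel across runs.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .io import quantity_column

log = logging.getLogger(__name__)

__all__ = [
    "build_peptide_matrix",
    "maxlfq",
    "quantify_all",
    "compute_ratios",
    "precursor_label_ratio",
]


def build_peptide_matrix(table: pd.DataFrame, protein_group: str, quant_source: str = "MS2"):
    """Precursor x (run, channel) intensity matrix for one protein group.

    Duplicate (precursor, column) observations are aggregated by maximum;
    columns without any observation are omitted.  Returns
    ``(matrix, precursor_index, columns)`` where ``matrix`` is a float
    ndarray with NaN for absent values and ``columns`` a list of
    (run, channel) tuples.
    """
    qcol = quantity_column(quant_source)
    sub = table.loc[table["protein_group"] == protein_group]
    if sub.empty:
        raise LookupError(f"protein group {protein_group!r} not present in table")
    wide = sub.pivot_table(
        index=["modified_sequence", "charge"],
        columns=["run", "channel"],
        values=qcol,
        aggfunc="max",
    )
    wide = wide.dropna(axis=1, how="all")
    return wide.to_numpy(float), list(wide.index), list(wide.columns)


def maxlfq(matrix: np.ndarray, min_shared_peptides: int = 1) -> np.ndarray:
    """MaxLFQ abundances (linear scale) for the columns of one protein.

    ``matrix`` is precursors x columns with NaN (or 0) marking absence.
    Returns one linear-scale abundance per column; NaN for columns with
    no observation.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.size == 0:
        raise ValueError("empty peptide matrix")
    X = np.where(X > 0, X, np.nan)
    if not np.isfinite(X).any():
        raise ValueError("peptide matrix has no observed intensity")

    L = np.log2(X)
    present = np.isfinite(L)
    p, c = L.shape
    out = np.full(c, np.nan)
    observed = present.any(axis=0)
    col_sums = np.nansum(X, axis=0)

    # Pairwise median log2 ratios and sharing counts.
    diff = L[:, None, :] - L[:, :, None]  # [k, a, b] = log2 I_kb - log2 I_ka
    shared = (present[:, None, :] & present[:, :, None]).sum(axis=0)
    np.fill_diagonal(shared, 0)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = np.nanmedian(diff, axis=0)  # r[a, b] = median(x_b - x_a)

    adj = (shared >= max(1, min_shared_peptides)) & observed[:, None] & observed[None, :]
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)

    for comp in range(n_comp):
        cols = np.flatnonzero((labels == comp) & observed)
        if cols.size == 0:
            continue
        if cols.size == 1:
            out[cols[0]] = col_sums[cols[0]]
            continue
        sub_adj = adj[np.ix_(cols, cols)]
        sub_r = np.where(sub_adj, r[np.ix_(cols, cols)], 0.0)
        deg = sub_adj.sum(axis=1)
        lap = np.diag(deg.astype(float)) - sub_adj.astype(float)
        # normal equations: deg_i * x_i - sum_{a in N(i)} x_a = -sum_a r[i, a]
        rhs = -sub_r.sum(axis=1)
        x = np.linalg.pinv(lap) @ rhs
        # anchor: summed linear abundance = total observed intensity
        total = col_sums[cols].sum()
        x = x + np.log2(total / np.sum(2.0**x))
        out[cols] = 2.0**x
    return out


def _lfq_over_columns(values, rows, cols, n_cols, min_shared):
    """Assemble the dense matrix for one protein and run MaxLFQ."""
    mat = np.full((rows.max() + 1, n_cols), np.nan)
    mat[rows, cols] = values
    return maxlfq(mat, min_shared)


def quantify_all(
    table: pd.DataFrame,
    quant_source: str = "MS2",
    mode: str = "joint",
    min_shared_peptides: int = 1,
) -> pd.DataFrame:
    """MaxLFQ quantification of every protein group in a filtered table.

    Parameters
    ----------
    mode : "joint" runs MaxLFQ over all (run, channel) columns of a
        protein at once; "per_channel" runs it separately per SILAC
        channel across runs.

    Returns a DataFrame with columns protein_group, gene, sample (the
    run), channel, lfq_intensity, n_precursors.  ``n_precursors`` counts
    distinct (modified sequence, charge) species per protein group,
    ignoring channels and runs.
    """
    if mode not in {"joint", "per_channel"}:
        raise ValueError(f"mode must be 'joint' or 'per_channel', got {mode!r}")
    qcol = quantity_column(quant_source)
    if table.empty:
        return pd.DataFrame(
            columns=["protein_group", "gene", "sample", "channel", "lfq_intensity", "n_precursors"]
        )

    df = table[["protein_group", "gene", "modified_sequence", "charge", "run", "channel", qcol]].copy()
    df = df.dropna(subset=[qcol])
    df = df[df[qcol] > 0]

    # Integer-code everything once; per-protein work is pure numpy.
    prot_codes, prot_index = pd.factorize(df["protein_group"], sort=True)
    prec_key = df["modified_sequence"].astype(str) + "/" + df["charge"].astype(str)
    prec_codes, _ = pd.factorize(prec_key)
    run_labels = pd.unique(df["run"])
    chan_labels = ["L", "M", "H"]
    run_codes = pd.Categorical(df["run"], categories=run_labels).codes
    chan_codes = pd.Categorical(df["channel"], categories=chan_labels).codes

    n_prec = (
        df.assign(_p=prot_codes, _k=prec_codes)
        .groupby("_p")["_k"]
        .nunique()
        .to_dict()
    )
    n_prec_by_acc = {prot_index[i]: n for i, n in n_prec.items()}
    gene_of = df.groupby("protein_group")["gene"].first()

    order = np.argsort(prot_codes, kind="stable")
    values = df[qcol].to_numpy()[order]
    prec = prec_codes[order]
    runs = run_codes[order]
    chans = chan_codes[order]
    bounds = np.searchsorted(prot_codes[order], np.arange(len(prot_index) + 1))

    records = []
    for pi in range(len(prot_index)):
        lo, hi = bounds[pi], bounds[pi + 1]
        v, k, rn, ch = values[lo:hi], prec[lo:hi], runs[lo:hi], chans[lo:hi]
        # densify precursor rows local to this protein
        _, krows = np.unique(k, return_inverse=True)
        if mode == "joint":
            col = rn * len(chan_labels) + ch
            used = np.unique(col)
            remap = np.searchsorted(used, col)
            mat = np.full((krows.max() + 1, used.size), np.nan)
            # duplicate (precursor, column) observations aggregate by max
            np.fmax.at(mat, (krows, remap), v)
            lfq = maxlfq(mat, min_shared_peptides)
            for j, u in enumerate(used):
                records.append(
                    (prot_index[pi], run_labels[u // len(chan_labels)],
                     chan_labels[u % len(chan_labels)], lfq[j])
                )
        else:
            for c in np.unique(ch):
                sel = ch == c
                used = np.unique(rn[sel])
                remap = np.searchsorted(used, rn[sel])
                kk = krows[sel]
                _, kk = np.unique(kk, return_inverse=True)
                mat = np.full((kk.max() + 1, used.size), np.nan)
                np.fmax.at(mat, (kk, remap), v[sel])
                lfq = maxlfq(mat, min_shared_peptides)
                for j, u in enumerate(used):
                    records.append(
                        (prot_index[pi], run_labels[u], chan_labels[c], lfq[j])
                    )

    out = pd.DataFrame(records, columns=["protein_group", "sample", "channel", "lfq_intensity"])
    out = out.dropna(subset=["lfq_intensity"]).reset_index(drop=True)
    out.insert(1, "gene", gene_of.reindex(out["protein_group"]).to_numpy())
    out["n_precursors"] = out["protein_group"].map(n_prec_by_acc).astype(int)
    out.attrs["quant_source"] = quant_source.upper()
    out.attrs["mode"] = mode
    return out


def compute_ratios(quants: pd.DataFrame, pair=("H", "M")) -> pd.DataFrame:
    """Per-protein per-sample log2 SILAC ratios from LFQ intensities.

    ``pair`` is (numerator, denominator).  The ratio is present only
    where both channels are quantified in that sample; no imputation.
    Returns a protein x sample DataFrame of log2 ratios.
    """
    num, den = pair
    if num == den:
        raise ValueError(f"numerator and denominator channel are both {num!r}")
    wide = quants.pivot_table(
        index="protein_group", columns=["sample", "channel"], values="lfq_intensity"
    )
    samples = sorted({s for s, _ in wide.columns})
    out = {}
    for s in samples:
        a = wide[(s, num)] if (s, num) in wide.columns else pd.Series(np.nan, index=wide.index)
        b = wide[(s, den)] if (s, den) in wide.columns else pd.Series(np.nan, index=wide.index)
        out[s] = np.log2(a / b)
    ratios = pd.DataFrame(out).dropna(how="all")
    ratios.attrs["pair"] = (num, den)
    ratios.attrs["quant_source"] = quants.attrs.get("quant_source")
    return ratios


def precursor_label_ratio(
    table: pd.DataFrame,
    labeled=("H", "M"),
    light: str = "L",
    quant_source: str = "MS2",
) -> pd.DataFrame:
    """Per-precursor log2(labeled / light) intensity ratios per run.

    One ratio per precursor per run per labeled channel, where both the
    labeled and the light intensity are observed.  These distributions
    quantify enrichment of newly synthesized (labeled) over pre-existing
    (light) protein.  Returns a long DataFrame (run, channel,
    modified_sequence, charge, log2_ratio).
    """
    qcol = quantity_column(quant_source)
    wide = table.pivot_table(
        index=["run", "modified_sequence", "charge"],
        columns="channel",
        values=qcol,
        aggfunc="max",
    )
    frames = []
    for ch in labeled:
        if ch not in wide.columns or light not in wide.columns:
            continue
        ratio = np.log2(wide[ch] / wide[light]).dropna()
        f = ratio.reset_index()
        f.columns = ["run", "modified_sequence", "charge", "log2_ratio"]
        f.insert(1, "channel", ch)
        frames.append(f)
    if not frames:
        log.warning("no (labeled, light) precursor pairs found; empty ratio distribution")
        return pd.DataFrame(columns=["run", "channel", "modified_sequence", "charge", "log2_ratio"])
    return pd.concat(frames, ignore_index=True)
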