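"""Reading, writing and filtering of channel-resolved precursor tables.

Two TSV dialects are supported: ``diann_channels`` (the column names of
DIA-NN's channel-resolved precursor matrices, e.g. ``Protein.Group``,
``Channel.Q.Value``) and ``simple`` (snake_case equivalents).  Tables are
held as pandas DataFrames with canonical snake_case columns; provenance
is carried in ``DataFrame.attrs``.

Filtering follows the standard stringent plexDIA recipe: contaminant
protein groups are removed, then precursors are kept only when the
precursor FDR q-value, the channel q-value and the translated q-value
are all strictly below their thresholds (default 0.01 each).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "COLUMNS",
    "FormatError",
    "FilterConfig",
    "read_precursor_table",
    "write_precursor_table",
    "load_contaminants",
    "remove_contaminants",
    "apply_qvalue_filters",
    "quantity_column",
]

#: canonical snake_case column names, in table order
COLUMNS = [
    "protein_group",
    "gene",
    "stripped_sequence",
    "modified_sequence",
    "charge",
    "channel",
    "run",
    "ms1_quantity",
    "ms2_quantity",
    "q_value",
    "channel_q_value",
    "translated_q_value",
]

_DIANN = {
    "Protein.Group": "protein_group",
    "Genes": "gene",
    "Stripped.Sequence": "stripped_sequence",
    "Modified.Sequence": "modified_sequence",
    "Precursor.Charge": "charge",
    "Channel": "channel",
    "Run": "run",
    "Ms1.Translated": "ms1_quantity",
    "Precursor.Translated": "ms2_quantity",
    "Q.Value": "q_value",
    "Channel.Q.Value": "channel_q_value",
    "Translated.Q.Value": "translated_q_value",
}

#: q-value columns a "simple" (MaxQuant-style) table may legitimately lack
_OPTIONAL_SIMPLE = {"q_value", "channel_q_value", "translated_q_value", "gene"}

_NUMERIC = ["charge", "ms1_quantity", "ms2_quantity", "q_value", "channel_q_value", "translated_q_value"]


class FormatError(ValueError):
    """An input table does not conform to the declared dialect."""


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds and contaminant rules for precursor-level filtering."""

    max_q: float = 0.01
    max_channel_q: float = 0.01
    max_translated_q: float = 0.01
    contaminant_ids: frozenset = frozenset()
    contaminant_prefix: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "contaminant_ids", frozenset(self.contaminant_ids))
        for name in ("max_q", "max_channel_q", "max_translated_q"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1], got {v!r}")


def quantity_column(quant_source: str) -> str:
    """Map an MS1/MS2 quantity selection to its canonical column."""
    source = quant_source.upper()
    if source not in {"MS1", "MS2"}:
        raise ValueError(f"quant_source must be 'MS1' or 'MS2', got {quant_source!r}")
    return "ms1_quantity" if source == "MS1" else "ms2_quantity"


def read_precursor_table(
    path,
    quant_source: str = "MS2",
    dialect: str = "diann_channels",
    channel_map: dict | None = None,
) -> pd.DataFrame:
    """Read a channel-resolved precursor TSV into canonical form.

    Parameters
    ----------
    path : file path
    quant_source : "MS1" or "MS2" — recorded on the table and used by all
        downstream quantification.
    dialect : "diann_channels" or "simple".
    channel_map : optional mapping of raw channel labels to {L, M, H}
        (e.g. ``{"Lys8/Arg10": "H"}``); identity on L/M/H by default.

    Rows in which both quantities are absent are dropped (count logged).
    """
    quantity_column(quant_source)  # validate early
    df = pd.read_csv(path, sep="\t", dtype=str)

    if dialect == "diann_channels":
        missing = [c for c in _DIANN if c not in df.columns]
        if missing:
            raise FormatError(f"missing required column(s) {missing} in {path}")
        df = df.rename(columns=_DIANN)[COLUMNS]
    elif dialect == "simple":
        missing = [c for c in COLUMNS if c not in df.columns and c not in _OPTIONAL_SIMPLE]
        if missing:
            raise FormatError(f"missing required column(s) {missing} in {path}")
        absent_q = [c for c in _OPTIONAL_SIMPLE - {"gene"} if c not in df.columns]
        if absent_q:
            log.warning(
                "simple dialect table %s lacks q-value column(s) %s; "
                "those filters will treat every row as passing", path, absent_q,
            )
        for c in COLUMNS:
            if c not in df.columns:
                df[c] = np.nan
        df = df[COLUMNS]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    for c in _NUMERIC:
        raw = df[c]
        converted = pd.to_numeric(raw, errors="coerce")
        bad = converted.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise FormatError(f"unparseable numeric value {raw[bad.idxmax()]!r} in column {c!r} at line {line} of {path}")
        df[c] = converted
    df["charge"] = df["charge"].astype("int64")

    cmap = channel_map or {}
    df["channel"] = df["channel"].map(lambda ch: cmap.get(ch, ch))
    unknown = set(df["channel"].unique()) - {"L", "M", "H"}
    if unknown:
        raise FormatError(f"unrecognized channel label(s) {sorted(unknown)}; provide a channel_map")

    both_absent = df["ms1_quantity"].isna() & df["ms2_quantity"].isna()
    if both_absent.any():
        log.info("dropped %d row(s) with no quantity in %s", int(both_absent.sum()), path)
        df = df.loc[~both_absent]

    df = df.reset_index(drop=True)
    df.attrs["quant_source"] = quant_source.upper()
    df.attrs["source"] = str(path)
    df.attrs["filters"] = []
    return df


def write_precursor_table(table: pd.DataFrame, path, dialect: str = "simple") -> None:
    """Write a canonical table back to TSV in the requested dialect."""
    if dialect == "simple":
        table[COLUMNS].to_csv(path, sep="\t", index=False)
    elif dialect == "diann_channels":
        inv = {v: k for k, v in _DIANN.items()}
        table[COLUMNS].rename(columns=inv).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def load_contaminants(path) -> frozenset:
    """Read a contaminant accession list (one accession per line)."""
    with open(path) as fh:
        return frozenset(line.strip() for line in fh if line.strip())


def _is_contaminant(group: str, cfg: FilterConfig) -> bool:
    # A multi-accession group is contaminant if ANY member matches.
    for acc in str(group).split(";"):
        if acc in cfg.contaminant_ids:
            return True
        if cfg.contaminant_prefix and acc.startswith(cfg.contaminant_prefix):
            return True
    return False


def remove_contaminants(table: pd.DataFrame, cfg: FilterConfig) -> pd.DataFrame:
    """Drop records whose protein group matches the contaminant rules."""
    if not cfg.contaminant_ids and not cfg.contaminant_prefix:
        out = table.copy()
        out.attrs = dict(table.attrs)
        return out
    groups = table["protein_group"].unique()
    bad = {g for g in groups if _is_contaminant(g, cfg)}
    mask = table["protein_group"].isin(bad)
    log.info("removed %d contaminant row(s) (%d group(s))", int(mask.sum()), len(bad))
    out = table.loc[~mask].reset_index(drop=True)
    out.attrs = dict(table.attrs)
    out.attrs["filters"] = list(table.attrs.get("filters", [])) + [
        {"stage": "contaminants", "removed_rows": int(mask.sum())}
    ]
    return out


def apply_qvalue_filters(table: pd.DataFrame, cfg: FilterConfig) -> pd.DataFrame:
    """Keep records with all three q-values strictly below threshold.

    A q-value exactly at a threshold is removed (strict "<").  Absent
    (NaN) q-values pass, so simple-dialect tables without channel
    q-values survive unchanged — the reader warns about this.
    """
    removed = {}
    mask = pd.Series(True, index=table.index)
    for col, thr in [
        ("q_value", cfg.max_q),
        ("channel_q_value", cfg.max_channel_q),
        ("translated_q_value", cfg.max_translated_q),
    ]:
        ok = table[col].isna() | (table[col] < thr)
        removed[col] = int((mask & ~ok).sum())
        mask &= ok
    log.info("q-value filters removed rows: %s", removed)
    out = table.loc[mask].reset_index(drop=True)
    out.attrs = dict(table.attrs)
    out.attrs["filters"] = list(table.attrs.get("filters", [])) + [
        {"stage": "q_value_filters", "removed_rows": removed}
    ]
    return out
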