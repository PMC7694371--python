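"""Reading differential-expression inputs and harmonising identifiers.

The unit of exchange between stages is a pandas DataFrame.  LFC tables carry
columns ``feature_id`` (platform-native identifier), optionally ``gene_id``
(harmonised identifier), and ``lfc`` (log2 fold change; positive = higher in
the high-grade group — the sign convention is fixed at ingestion and never
flipped downstream).  An adjusted p-value column is carried through if present
but is not used by the rank statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

COLLAPSE_RULES = ("max_abs", "mean")


@dataclass
class ExpressionMatrix:
    """Genes x samples grid of log2-scale intensities plus group labels.

    ``values``: DataFrame indexed by gene/feature id, one column per sample.
    ``groups``: Series mapping sample name -> group label (two groups).
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without group assignment: {missing[:5]}")

    def samples_in(self, group: str) -> list[str]:
        labels = self.groups.loc[list(self.values.columns)]
        hit = [s for s, g in labels.items() if g == group]
        if not hit:
            raise KeyError(f"unknown or empty group label: {group!r}")
        return hit


def read_lfc_table(
    path,
    feature_col: str = "feature_id",
    lfc_col: str = "lfc",
    adj_p_col: str | None = None,
) -> tuple[pd.DataFrame, int]:
    """Read a TSV of per-feature log2 fold changes.

    Rows with a missing or non-numeric LFC are dropped; the drop count is
    returned alongside the table and logged.  Duplicate feature ids are
    retained here — collapsing to one row per gene happens after identifier
    mapping (see :func:`collapse_duplicates`).

    Returns ``(frame, n_dropped)`` where ``frame`` has columns ``feature_id``,
    ``lfc`` and, when requested, ``adj_p``.
    """
    raw = pd.read_csv(path, sep="\t", dtype={feature_col: str})
    for col in (feature_col, lfc_col) + ((adj_p_col,) if adj_p_col else ()):
        if col not in raw.columns:
            raise KeyError(f"column {col!r} not found in {path} (header: {list(raw.columns)})")
    out = pd.DataFrame({"feature_id": raw[feature_col].astype(str)})
    out["lfc"] = pd.to_numeric(raw[lfc_col], errors="coerce")
    if adj_p_col:
        out["adj_p"] = pd.to_numeric(raw[adj_p_col], errors="coerce")
    keep = np.isfinite(out["lfc"].to_numpy()) & (out["feature_id"].str.len() > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("read_lfc_table(%s): dropped %d rows with missing/non-numeric LFC", path, n_dropped)
    return out.loc[keep].reset_index(drop=True), n_dropped


def read_mapping_table(path) -> pd.DataFrame:
    """Read a two-column TSV ``feature_id<TAB>gene_id`` (header required).

    Many-to-many pairs are permitted; exact duplicate pairs are removed.
    """
    m = pd.read_csv(path, sep="\t", dtype=str)
    if not {"feature_id", "gene_id"}.issubset(m.columns):
        raise KeyError(f"mapping table {path} must have columns feature_id, gene_id")
    m = m[["feature_id", "gene_id"]].dropna().drop_duplicates()
    m = m[(m["feature_id"].str.len() > 0) & (m["gene_id"].str.len() > 0)]
    return m.reset_index(drop=True)


def map_to_gene_ids(
    records: pd.DataFrame,
    mapping: pd.DataFrame,
    fallback: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, int]:
    """Attach gene ids via a primary mapping, then a fallback mapping.

    Mirrors a two-stage conversion route (direct database mapping, then an
    alternative nomenclature hop for the remainder).  A feature mapping to k
    genes yields k records.  Features absent from both tables are dropped and
    counted, never silently discarded.

    Returns ``(frame_with_gene_id, n_unmapped_features)``.
    """
    if mapping.empty:
        raise ValueError("primary mapping table is empty")
    hit = records.merge(mapping, on="feature_id", how="inner")
    unmapped = records[~records["feature_id"].isin(set(mapping["feature_id"]))]
    if fallback is not None and not unmapped.empty:
        rescue = unmapped.merge(fallback, on="feature_id", how="inner")
        hit = pd.concat([hit, rescue], ignore_index=True)
        unmapped = unmapped[~unmapped["feature_id"].isin(set(fallback["feature_id"]))]
    n_unmapped = int(unmapped["feature_id"].nunique())
    if n_unmapped:
        log.info("map_to_gene_ids: %d features unmapped after primary+fallback; dropped", n_unmapped)
    return hit.reset_index(drop=True), n_unmapped


def collapse_duplicates(records: pd.DataFrame, rule: str = "max_abs") -> pd.DataFrame:
    """Collapse to one LFC per gene_id.

    ``max_abs`` keeps the LFC with the largest absolute value (ties broken
    toward the larger signed value) — preserves the strongest signal, which is
    what a rank statistic keys on.  ``mean`` takes the arithmetic mean.
    Idempotent: collapsing a collapsed table is a no-op.
    """
    if rule not in COLLAPSE_RULES:
        raise ValueError(f"unknown collapse rule {rule!r}; expected one of {COLLAPSE_RULES}")
    if "gene_id" not in records.columns:
        raise ValueError("records must carry gene_id before collapsing")
    if rule == "mean":
        out = records.groupby("gene_id", as_index=False)["lfc"].mean()
    else:
        ordered = records.assign(_abs=records["lfc"].abs()).sort_values(
            ["gene_id", "_abs", "lfc"], kind="mergesort"
        )
        out = ordered.groupby("gene_id", as_index=False).last()[["gene_id", "lfc"]]
    return out.sort_values("gene_id", kind="mergesort").reset_index(drop=True)


def intersect_levels(transcripts: pd.DataFrame, proteins: pd.DataFrame) -> pd.DataFrame:
    """Join the two collapsed tables on gene_id, keeping the shared genes.

    Output columns: ``gene_id``, ``lfc_transcript``, ``lfc_protein``.  An
    empty intersection is a hard error — nothing downstream can run on it.
    """
    for name, df in (("transcripts", transcripts), ("proteins", proteins)):
        if df["gene_id"].duplicated().any():
            raise ValueError(f"{name} table not collapsed: duplicate gene_id present")
    merged = transcripts.rename(columns={"lfc": "lfc_transcript"})[
        ["gene_id", "lfc_transcript"]
    ].merge(
        proteins.rename(columns={"lfc": "lfc_protein"})[["gene_id", "lfc_protein"]],
        on="gene_id",
        how="inner",
    )
    if merged.empty:
        raise ValueError("no gene_ids shared between the two omic levels")
    log.info("intersect_levels: %d shared genes", len(merged))
    return merged.sort_values("gene_id", kind="mergesort").reset_index(drop=True)


def compute_lfc(
    matrix: ExpressionMatrix, group_a: str, group_b: str
) -> tuple[pd.DataFrame, int]:
    """Per-gene log2 fold change: mean(group_a) - mean(group_b).

    Values are assumed to be on log2 scale already, so the group-mean
    difference is the LFC.  Genes with any missing value in either group are
    dropped listwise and counted.
    """
    cols_a = matrix.samples_in(group_a)
    cols_b = matrix.samples_in(group_b)
    va = matrix.values[cols_a].to_numpy(dtype=float)
    vb = matrix.values[cols_b].to_numpy(dtype=float)
    ok = np.isfinite(va).all(axis=1) & np.isfinite(vb).all(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.info("compute_lfc: dropped %d genes with missing values", n_dropped)
    lfc = va[ok].mean(axis=1) - vb[ok].mean(axis=1)
    out = pd.DataFrame(
        {"feature_id": matrix.values.index[ok].astype(str), "lfc": lfc}
    ).reset_index(drop=True)
    return out, n_dropped


def read_expression_matrix(matrix_path, groups_path) -> ExpressionMatrix:
    """Read a genes-in-rows TSV and a two-column ``sample<TAB>group`` TSV."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    g = pd.read_csv(groups_path, sep="\t", dtype=str)
    if not {"sample", "group"}.issubset(g.columns):
        raise KeyError(f"group table {groups_path} must have columns sample, group")
    return ExpressionMatrix(values, g.set_index("sample")["group"])
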