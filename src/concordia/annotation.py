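"""Overlap of ranked gene lists with external reference memberships.

Two references are supported: a plasma-proteome membership list (proteins
detectable in blood plasma, used to flag tumour proteins plausibly acquired
from the circulation rather than synthesised in situ) and a drug-gene
interaction table in the style of a druggable-genome database, filterable to
regulator-approved compounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class ReferenceSet:
    """A named membership list, e.g. the plasma-detectable proteome.

    ``source_size`` records the nominal size of the full published reference
    (which may exceed the members supplied here).
    """

    name: str
    members: frozenset
    source_size: int | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"reference set {self.name!r} has no members")


@dataclass
class OverlapResult:
    query_size: int
    hits: pd.DataFrame
    hit_count: int


@dataclass
class DrugTargetResult:
    """Two-stage drug-target selection: interacting genes, then the
    concordantly upregulated subset."""

    stage1_count: int
    stage2_count: int
    table: pd.DataFrame


def read_reference_set(path, name: str, source_size: int | None = None) -> ReferenceSet:
    """Read a one-column membership TSV (column ``gene_id``, header required)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "gene_id" not in df.columns:
        raise KeyError(f"reference file {path} must have a gene_id column")
    members = frozenset(df["gene_id"].dropna())
    return ReferenceSet(name=name, members=members, source_size=source_size)


def read_drug_interactions(path, approved_only: bool = True) -> pd.DataFrame:
    """Read a TSV of (gene_id, drug_name, approved) interaction rows.

    ``approved`` is parsed as boolean-ish text; with ``approved_only`` the
    table is restricted to approved compounds, mirroring a regulator-approval
    filter.  Duplicate (gene, drug) pairs are dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"gene_id", "drug_name"}
    if not need.issubset(df.columns):
        raise KeyError(f"drug table {path} must have columns gene_id, drug_name")
    if "approved" in df.columns:
        df["approved"] = df["approved"].str.lower().isin({"true", "1", "yes", "y"})
    else:
        df["approved"] = True
    if approved_only:
        df = df[df["approved"]]
    return df.drop_duplicates(["gene_id", "drug_name"]).reset_index(drop=True)


def plasma_overlap(top_discordant: pd.DataFrame, plasma: ReferenceSet) -> OverlapResult:
    """Which of the top discordant (protein-up) genes are plasma-detectable?

    ``top_discordant`` should come from the discordant_protein_up top-k
    selection.  Hits are ordered by avg_rank_discordant descending (strongest
    discordance first), with gene_id as a deterministic tie-break, and retain
    the full ranked-record columns for table-style reporting.
    """
    hits = top_discordant[top_discordant["gene_id"].isin(plasma.members)]
    hits = hits.sort_values(
        ["avg_rank_discordant", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return OverlapResult(
        query_size=len(top_discordant), hits=hits, hit_count=len(hits)
    )


def drug_target_filter(
    table: pd.DataFrame,
    interactions: pd.DataFrame,
    require_concordant_up_sign: bool = True,
) -> DrugTargetResult:
    """Drug-target candidates among concordantly upregulated genes.

    Stage 1 keeps genes with at least one interaction in the (already
    approval-filtered) table; stage 2 keeps the subset with a concordant
    increase, operationalised as lfc_transcript > 0 and lfc_protein > 0.
    Drug names per gene are reported semicolon-joined, sorted.
    """
    interacting = (
        interactions.groupby("gene_id")["drug_name"]
        .apply(lambda s: ";".join(sorted(set(s))))
        .rename("drugs")
    )
    stage1 = table.merge(interacting, left_on="gene_id", right_index=True, how="inner")
    if require_concordant_up_sign:
        stage2 = stage1[(stage1["lfc_transcript"] > 0) & (stage1["lfc_protein"] > 0)]
    else:
        stage2 = stage1
    if "avg_rank_concordant" in stage2.columns:
        stage2 = stage2.sort_values(
            ["avg_rank_concordant", "gene_id"], kind="mergesort"
        )
    return DrugTargetResult(
        stage1_count=len(stage1),
        stage2_count=len(stage2),
        table=stage2.reset_index(drop=True),
    )
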