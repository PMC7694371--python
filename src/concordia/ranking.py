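"""Average-rank concordance and discordance statistics over paired LFCs.

Both LFC columns are converted to ranks (1 = most extreme in the chosen
direction) and averaged under direction-specific orderings:

* concordance: transcript descending + protein descending.  A low average
  rank marks concordant upregulation, a high one concordant downregulation.
* discordance: transcript descending + protein ascending.  A high average
  rank marks genes with protein up / transcript down; a low one protein
  down / transcript up.

Being rank-based, the statistics are invariant to any strictly increasing
transform of either LFC column, which is what makes them robust to the very
different spreads of transcript and protein LFC distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

RANK_COLUMNS = (
    "rank_t_desc",
    "rank_p_desc",
    "rank_p_asc",
    "avg_rank_concordant",
    "avg_rank_discordant",
)

TOP_K_MODES = (
    "concordant_up",
    "concordant_down",
    "discordant_protein_up",
    "discordant_protein_down",
)

# sign pattern required by each mode when sign_filter is on
_SIGN_PATTERN = {
    "concordant_up": lambda t, p: (t > 0) & (p > 0),
    "concordant_down": lambda t, p: (t < 0) & (p < 0),
    "discordant_protein_up": lambda t, p: (t < 0) & (p > 0),
    "discordant_protein_down": lambda t, p: (t > 0) & (p < 0),
}


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of paired LFCs with a two-sided t-approximation p."""

    r: float
    p_value: float
    n: int


def rank_values(
    values, order: str = "descending", ties: str = "midrank"
) -> np.ndarray:
    """Rank a vector so the most extreme value gets rank 1.

    ``descending``: largest value -> 1.  ``ascending``: smallest value -> 1.
    Ties receive the mean of the positions they span (midrank), so the rank
    sum is always N(N+1)/2.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("rank_values expects a non-empty 1-d vector")
    if not np.isfinite(v).all():
        raise ValueError("rank_values: non-finite input")
    if order not in ("descending", "ascending"):
        raise ValueError(f"unknown order {order!r}")
    if ties != "midrank":
        raise ValueError(f"unknown tie rule {ties!r}")
    return stats.rankdata(-v if order == "descending" else v, method="average")


def average_rank(rank_a, rank_b):
    """The integration statistic: mean of two per-level ranks.

    Scalar or element-wise on arrays.  Which orderings the two ranks come
    from decides the reading: descending+descending gives the concordance
    statistic, descending (transcript) + ascending (protein) the discordance
    statistic.
    """
    return (np.asarray(rank_a, dtype=float) + np.asarray(rank_b, dtype=float)) / 2.0


def score_concordance(table: pd.DataFrame) -> pd.DataFrame:
    """Add rank_t_desc, rank_p_desc and avg_rank_concordant columns."""
    out = _checked(table).copy()
    out["rank_t_desc"] = rank_values(out["lfc_transcript"], "descending")
    out["rank_p_desc"] = rank_values(out["lfc_protein"], "descending")
    out["avg_rank_concordant"] = average_rank(out["rank_t_desc"], out["rank_p_desc"])
    return out


def score_discordance(table: pd.DataFrame) -> pd.DataFrame:
    """Add rank_t_desc, rank_p_asc and avg_rank_discordant columns."""
    out = _checked(table).copy()
    out["rank_t_desc"] = rank_values(out["lfc_transcript"], "descending")
    out["rank_p_asc"] = rank_values(out["lfc_protein"], "ascending")
    out["avg_rank_discordant"] = average_rank(out["rank_t_desc"], out["rank_p_asc"])
    return out


def rank_table(table: pd.DataFrame) -> pd.DataFrame:
    """Full ranked table with both average-rank statistics.

    Columns: gene_id, lfc_transcript, lfc_protein, rank_t_desc, rank_p_desc,
    rank_p_asc, avg_rank_concordant, avg_rank_discordant.
    """
    con = score_concordance(table)
    dis = score_discordance(table)
    con["rank_p_asc"] = dis["rank_p_asc"]
    con["avg_rank_discordant"] = dis["avg_rank_discordant"]
    cols = ["gene_id", "lfc_transcript", "lfc_protein", *RANK_COLUMNS]
    extra = [c for c in con.columns if c not in cols]
    return con[cols + extra]


def top_k(
    table: pd.DataFrame, k: int, mode: str, sign_filter: bool = True
) -> pd.DataFrame:
    """Select the k most extreme genes of a ranked table in one direction.

    With ``sign_filter`` on (default), candidates are first restricted to the
    direction's literal sign pattern (e.g. discordant_protein_up requires
    lfc_protein > 0 and lfc_transcript < 0) and the top k of the remainder
    are taken; with it off the selection is by average rank alone.  Boundary
    ties are broken by gene_id lexicographically, so the selection is
    deterministic.
    """
    if mode not in TOP_K_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {TOP_K_MODES}")
    n = len(table)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    key, ascending = {
        "concordant_up": ("avg_rank_concordant", True),
        "concordant_down": ("avg_rank_concordant", False),
        "discordant_protein_up": ("avg_rank_discordant", False),
        "discordant_protein_down": ("avg_rank_discordant", True),
    }[mode]
    if key not in table.columns:
        raise ValueError(f"table lacks column {key!r}; run rank_table first")
    cand = table
    if sign_filter:
        mask = _SIGN_PATTERN[mode](
            table["lfc_transcript"].to_numpy(), table["lfc_protein"].to_numpy()
        )
        cand = table.loc[mask]
    ordered = cand.sort_values(
        [key, "gene_id"], ascending=[ascending, True], kind="mergesort"
    )
    return ordered.head(k).reset_index(drop=True)


def lfc_correlation(table: pd.DataFrame) -> CorrelationResult:
    """Sample Pearson correlation between the two LFC columns.

    The p-value is the two-sided t-approximation with n-2 degrees of freedom.
    Degenerate (constant) columns are rejected with an error naming the
    offending level.
    """
    t = np.asarray(table["lfc_transcript"], dtype=float)
    p = np.asarray(table["lfc_protein"], dtype=float)
    if t.size < 3:
        raise ValueError("lfc_correlation requires n >= 3")
    for name, v in (("lfc_transcript", t), ("lfc_protein", p)):
        if np.ptp(v) == 0.0:
            raise ValueError(f"{name} is constant; correlation undefined")
    res = stats.pearsonr(t, p)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue), n=t.size)


def _checked(table: pd.DataFrame) -> pd.DataFrame:
    if len(table) == 0:
        raise ValueError("empty integrated table")
    missing = {"gene_id", "lfc_transcript", "lfc_protein"} - set(table.columns)
    if missing:
        raise ValueError(f"integrated table lacks columns {sorted(missing)}")
    if table["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_id in integrated table")
    return table
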