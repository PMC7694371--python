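"""End-to-end orchestration: ingest -> rank -> annotate -> enrich -> report.

Every artefact is a TSV with fixed column names; floats are rendered with 6
significant digits so repeated runs under the same configuration and seed
produce byte-identical files.  A JSON manifest lists every file written with
its row count, and a plain-text run log records dropped/unmapped counts, the
intersection size, the LFC correlation, and summary counts of each stage.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from concordia import annotation, enrichment, ingest, ranking

_FLOAT_FMT = "%.6g"

HIGHLIGHT_CLASSES = (
    "concordant_up",
    "concordant_down",
    "discordant_hi",
    "discordant_lo",
    "background",
)

_HIGHLIGHT_MODE = {
    "concordant_up": "concordant_up",
    "concordant_down": "concordant_down",
    "discordant_hi": "discordant_protein_up",
    "discordant_lo": "discordant_protein_down",
}


class PipelineError(RuntimeError):
    """Stage-named failure of the orchestrated pipeline."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All knobs of one pipeline run; every default overridable via YAML.

    Reporting defaults follow the emulated study: top-10 gene tables per
    direction, top-100 discordant genes for the plasma overlap, per-level
    FDR threshold 0.2, 1000 permutations.
    """

    transcripts: str = ""
    proteins: str = ""
    out_dir: str = "concordia_out"
    mapping: str | None = None
    fallback_mapping: str | None = None
    gene_sets: str | None = None
    plasma: str | None = None
    drugs: str | None = None
    feature_col: str = "feature_id"
    lfc_col: str = "lfc"
    collapse_rule: str = "max_abs"
    ties: str = "midrank"
    top_k_report: int = 10
    top_k_plasma: int = 100
    sign_filter: bool = True
    fdr_threshold: float = 0.2
    n_perm: int = 1000
    weight: float = 1.0
    min_set_size: int = 5
    exclude_sets: tuple = ()
    plasma_source_size: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_threshold < 1.0:
            raise ValueError("fdr_threshold must lie in (0, 1)")
        if min(self.top_k_report, self.top_k_plasma) < 1:
            raise ValueError("top-k values must be positive")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise KeyError(f"unknown config keys in {path}: {sorted(unknown)}")
        raw.update(overrides)
        if "exclude_sets" in raw and raw["exclude_sets"] is not None:
            raw["exclude_sets"] = tuple(raw["exclude_sets"])
        return cls(**raw)


def export_scatter_data(
    table: pd.DataFrame, k: int, sign_filter: bool = True
) -> pd.DataFrame:
    """Plot-ready scatter table: one row per gene with a highlight class.

    x = lfc_transcript, y = lfc_protein; the top-k genes of each direction
    are labelled concordant_up / concordant_down / discordant_hi (protein up,
    transcript down) / discordant_lo, everything else background.  Classes
    are assigned in that priority order, so each gene carries exactly one.
    ``k = 0`` labels everything background.
    """
    out = table[["gene_id", "lfc_transcript", "lfc_protein"]].copy()
    label = pd.Series("background", index=table["gene_id"].to_numpy(dtype=object))
    if k > 0:
        for cls in HIGHLIGHT_CLASSES[:4]:
            chosen = ranking.top_k(table, k, _HIGHLIGHT_MODE[cls], sign_filter=sign_filter)
            fresh = [g for g in chosen["gene_id"] if label.loc[g] == "background"]
            label.loc[fresh] = cls
    out["highlight"] = label.loc[out["gene_id"].to_numpy(dtype=object)].to_numpy()
    return out


def run_pipeline(config: RunConfig, dry_run: bool = False) -> dict:
    """Execute the full pipeline; returns the artifact manifest.

    Any stage error aborts with a stage-named :class:`PipelineError`;
    whatever was already written stays on disk next to a ``.partial``
    marker.  With ``dry_run`` nothing is written and the manifest reports
    the files that a real run would produce.
    """
    out = Path(config.out_dir)
    if not dry_run:
        out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "files": {}}
    log_lines: list[str] = [f"concordia run (seed={config.seed})"]

    def write(name: str, frame: pd.DataFrame, index: bool = False) -> None:
        manifest["files"][name] = {"rows": int(len(frame))}
        if not dry_run:
            frame.to_csv(out / name, sep="\t", index=index, float_format=_FLOAT_FMT)

    def fail(stage: str, exc: Exception):
        if not dry_run:
            (out / ".partial").write_text(f"failed in stage {stage}\n")
        raise PipelineError(stage, exc) from exc

    # ingest ---------------------------------------------------------------
    try:
        integrated = _ingest(config, log_lines)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        fail("ingest", exc)

    # rank -----------------------------------------------------------------
    try:
        ranked = ranking.rank_table(integrated)
        corr = ranking.lfc_correlation(ranked)
        log_lines.append(
            f"rank: N={corr.n} genes, Pearson r={corr.r:.4f} (p={corr.p_value:.3e})"
        )
        write("ranked_table.tsv", ranked)
        k = min(config.top_k_report, len(ranked))
        for cls in HIGHLIGHT_CLASSES[:4]:
            sel = ranking.top_k(ranked, k, _HIGHLIGHT_MODE[cls], config.sign_filter)
            write(f"top_{cls}.tsv", sel)
            log_lines.append(f"rank: top-{k} {cls}: " + ", ".join(sel["gene_id"].head(k)))
        write("scatter_data.tsv", export_scatter_data(ranked, k, config.sign_filter))
        corr_frame = pd.DataFrame(
            [{"r": corr.r, "p_value": corr.p_value, "n": corr.n}]
        )
        write("correlation.tsv", corr_frame)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail("rank", exc)

    # annotate -------------------------------------------------------------
    try:
        if config.plasma:
            plasma = annotation.read_reference_set(
                config.plasma, "plasma_proteome", config.plasma_source_size
            )
            top_dis = ranking.top_k(
                ranked,
                min(config.top_k_plasma, len(ranked)),
                "discordant_protein_up",
                config.sign_filter,
            )
            overlap = annotation.plasma_overlap(top_dis, plasma)
            write("plasma_overlap.tsv", overlap.hits)
            log_lines.append(
                f"annotate: plasma overlap {overlap.hit_count}/{overlap.query_size} "
                f"top discordant genes"
            )
        if config.drugs:
            interactions = annotation.read_drug_interactions(config.drugs)
            drug_res = annotation.drug_target_filter(ranked, interactions)
            write(
                "drug_targets.tsv",
                drug_res.table[
                    ["gene_id", "lfc_transcript", "lfc_protein", "avg_rank_concordant", "drugs"]
                ],
            )
            log_lines.append(
                f"annotate: {drug_res.stage1_count} genes with approved-drug "
                f"interactions, {drug_res.stage2_count} concordantly upregulated"
            )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail("annotate", exc)

    # enrich ---------------------------------------------------------------
    try:
        if config.gene_sets:
            sets = enrichment.read_gmt(config.gene_sets)
            seed_t, seed_p = np.random.SeedSequence(config.seed).spawn(2)
            per_level = {}
            for level, lfc_col, child in (
                ("transcript", "lfc_transcript", seed_t),
                ("protein", "lfc_protein", seed_p),
            ):
                scores = ranked.set_index("gene_id")[lfc_col]
                res = enrichment.preranked_gsea(
                    scores,
                    sets,
                    n_perm=config.n_perm,
                    weight=config.weight,
                    min_size=config.min_set_size,
                    seed=np.random.default_rng(child),
                    exclude=config.exclude_sets,
                )
                per_level[level] = res
                write(f"enrichment_{level}.tsv", res)
            dual = enrichment.dual_level_combine(
                per_level["transcript"], per_level["protein"], config.fdr_threshold
            )
            write("enrichment_dual.tsv", dual)
            n_pass = int(dual["passes_dual_fdr"].sum())
            log_lines.append(
                f"enrich: {len(dual)} sets tested, {n_pass} pass dual FDR < "
                f"{config.fdr_threshold:g} (implied combined p < "
                f"{enrichment.combined_significance_threshold(config.fdr_threshold):g})"
            )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail("enrich", exc)

    # report ---------------------------------------------------------------
    if not dry_run:
        (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
        manifest["files"]["run_log.txt"] = {"rows": len(log_lines)}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        partial = out / ".partial"
        if partial.exists():
            partial.unlink()
    else:
        manifest["files"]["run_log.txt"] = {"rows": len(log_lines)}
    return manifest


def _ingest(config: RunConfig, log_lines: list[str]) -> pd.DataFrame:
    levels = {}
    mapping = ingest.read_mapping_table(config.mapping) if config.mapping else None
    fallback = (
        ingest.read_mapping_table(config.fallback_mapping)
        if config.fallback_mapping
        else None
    )
    for level, path in (("transcript", config.transcripts), ("protein", config.proteins)):
        frame, n_dropped = ingest.read_lfc_table(
            path, feature_col=config.feature_col, lfc_col=config.lfc_col
        )
        if mapping is not None:
            frame, n_unmapped = ingest.map_to_gene_ids(frame, mapping, fallback)
        else:
            frame = frame.assign(gene_id=frame["feature_id"])
            n_unmapped = 0
        collapsed = ingest.collapse_duplicates(frame, config.collapse_rule)
        log_lines.append(
            f"ingest: {level}: {len(collapsed)} genes "
            f"({n_dropped} rows dropped, {n_unmapped} features unmapped)"
        )
        levels[level] = collapsed
    integrated = ingest.intersect_levels(levels["transcript"], levels["protein"])
    log_lines.append(f"ingest: intersection of both levels: {len(integrated)} genes")
    return integrated
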