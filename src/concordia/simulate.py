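"""Synthetic paired-LFC studies with planted structure.

The generator emulates the derived product of a two-cohort tumour-grade
contrast measured at the transcript and the protein level: one paired
log2-fold-change vector over ~3,600 shared genes with moderate positive
correlation, a wider and upward-shifted protein LFC distribution (mean 0.41)
against a narrower, centred transcript distribution (mean 0.0), and small
planted groups of strongly concordant and discordant genes whose identity is
recorded as ground truth.  Reference memberships (a plasma-proteome list and
a drug-interaction table) and gene-set collections are constructed around the
planted genes so that every downstream stage has a recoverable signal.

All generators are pure functions of (parameters, seed): a single top-level
seed is fanned out to per-stage child seeds via ``numpy.random.SeedSequence``
(spawn order: planted-gene labels, LFC draw, expression matrices, gene sets,
reference sets), so each stage is reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from concordia.annotation import ReferenceSet
from concordia.enrichment import GeneSetCollection, write_gmt
from concordia.ingest import ExpressionMatrix

_FLOAT_FMT = "%.6g"

# spawn order of per-stage child seeds
_STAGES = ("labels", "lfc", "expression", "gene_sets", "references")


@dataclass
class SyntheticTruth:
    """Generative parameters plus the planted gene labels they imply.

    Background LFC pairs are bivariate normal with correlation ``rho``,
    means ``(mean_t, mean_p)`` and scales ``(scale_t, scale_p)``; defaults
    mirror the emulated study: 3,598 shared genes, rho 0.35, transcript LFCs
    centred at 0, protein LFCs centred at 0.41 with the wider spread.
    Planted genes receive additive shifts of ``effect_multiplier`` times the
    level's scale: concordant up (+t, +p), concordant down (-t, -p),
    discordant (-t, +p: protein up, transcript down).  The scale defaults
    (0.5 transcript, 1.2 protein) are declared constants chosen so the
    protein spread dominates, as in the emulated data.
    """

    n_genes: int = 3598
    rho: float = 0.35
    mean_t: float = 0.0
    mean_p: float = 0.41
    scale_t: float = 0.5
    scale_p: float = 1.2
    n_concordant_up: int = 30
    n_concordant_down: int = 30
    n_discordant: int = 40
    effect_multiplier: float = 3.0
    n_plasma_planted: int = 21
    plasma_source_size: int = 1929
    planted_set_name: str = "PLANTED_CONCORDANT_UP"
    seed: int = 0

    gene_ids: tuple = field(init=False, repr=False)
    planted_concordant_up: tuple = field(init=False, repr=False)
    planted_concordant_down: tuple = field(init=False, repr=False)
    planted_discordant: tuple = field(init=False, repr=False)
    plasma_planted: tuple = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not -1.0 < self.rho < 1.0:
            raise ValueError(f"rho={self.rho} outside (-1, 1)")
        if min(self.scale_t, self.scale_p) <= 0:
            raise ValueError("scales must be positive")
        n_planted = self.n_concordant_up + self.n_concordant_down + self.n_discordant
        if self.n_genes < 10 * n_planted:
            raise ValueError(
                f"n_genes={self.n_genes} must be >= 10x total planted ({n_planted})"
            )
        if self.n_plasma_planted > self.n_discordant:
            raise ValueError("n_plasma_planted cannot exceed n_discordant")
        width = len(str(self.n_genes - 1))
        self.gene_ids = tuple(f"G{i:0{width}d}" for i in range(self.n_genes))
        rng = np.random.default_rng(self._child_seed("labels"))
        picks = rng.choice(self.n_genes, size=n_planted, replace=False)
        ids = np.asarray(self.gene_ids, dtype=object)[picks]
        a, b = self.n_concordant_up, self.n_concordant_up + self.n_concordant_down
        self.planted_concordant_up = tuple(sorted(ids[:a]))
        self.planted_concordant_down = tuple(sorted(ids[a:b]))
        self.planted_discordant = tuple(sorted(ids[b:]))
        self.plasma_planted = tuple(
            sorted(rng.choice(np.asarray(self.planted_discordant, dtype=object),
                              size=self.n_plasma_planted, replace=False))
        )

    # -- seed fan-out -------------------------------------------------------
    def _child_seed(self, stage: str) -> np.random.SeedSequence:
        children = np.random.SeedSequence(self.seed).spawn(len(_STAGES))
        return children[_STAGES.index(stage)]

    def rng_for(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(self._child_seed(stage))

    @property
    def delta_t(self) -> float:
        return self.effect_multiplier * self.scale_t

    @property
    def delta_p(self) -> float:
        return self.effect_multiplier * self.scale_p

    def to_dict(self) -> dict:
        d = {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if f.init
        }
        for key in ("planted_concordant_up", "planted_concordant_down",
                    "planted_discordant", "plasma_planted"):
            d[key] = list(getattr(self, key))
        return d


def simulate_paired_lfc(
    truth: SyntheticTruth | None = None, **params
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Draw one paired transcript/protein LFC study.

    Returns ``(transcripts, proteins, truth)`` where the two frames have
    columns feature_id, lfc (feature ids are already the harmonised gene
    ids — identifier mapping has no synthetic analogue here).
    """
    if truth is None:
        truth = SyntheticTruth(**params)
    rng = truth.rng_for("lfc")
    z = rng.standard_normal((truth.n_genes, 2))
    x_t = z[:, 0]
    x_p = truth.rho * z[:, 0] + np.sqrt(1.0 - truth.rho**2) * z[:, 1]
    lfc_t = truth.mean_t + truth.scale_t * x_t
    lfc_p = truth.mean_p + truth.scale_p * x_p

    index = {g: i for i, g in enumerate(truth.gene_ids)}
    up = [index[g] for g in truth.planted_concordant_up]
    down = [index[g] for g in truth.planted_concordant_down]
    dis = [index[g] for g in truth.planted_discordant]
    lfc_t[up] += truth.delta_t
    lfc_p[up] += truth.delta_p
    lfc_t[down] -= truth.delta_t
    lfc_p[down] -= truth.delta_p
    lfc_t[dis] -= truth.delta_t
    lfc_p[dis] += truth.delta_p

    transcripts = pd.DataFrame({"feature_id": truth.gene_ids, "lfc": lfc_t})
    proteins = pd.DataFrame({"feature_id": truth.gene_ids, "lfc": lfc_p})
    return transcripts, proteins, truth


def simulate_expression_matrix(
    lfc: pd.Series,
    n_a: int,
    n_b: int,
    noise_sd: float,
    rng: np.random.Generator,
    baseline: float = 8.0,
    group_a: str = "grade_III",
    group_b: str = "grade_I",
) -> ExpressionMatrix:
    """Log2-scale expression matrix whose group-mean difference targets ``lfc``.

    Group-a samples are centred at baseline + lfc per gene, group-b samples at
    baseline, with iid Gaussian noise of sd ``noise_sd`` — so a plain
    group-mean-difference LFC recovers the target with standard error
    ``noise_sd * sqrt(1/n_a + 1/n_b)`` per gene.
    """
    if min(n_a, n_b) < 2:
        raise ValueError("need at least 2 samples per group")
    genes = lfc.index.to_numpy(dtype=object)
    target = lfc.to_numpy(dtype=float)[:, None]
    a = baseline + target + noise_sd * rng.standard_normal((genes.size, n_a))
    b = baseline + noise_sd * rng.standard_normal((genes.size, n_b))
    samples = [f"{group_a}_{i + 1}" for i in range(n_a)] + [
        f"{group_b}_{i + 1}" for i in range(n_b)
    ]
    values = pd.DataFrame(np.hstack([a, b]), index=genes, columns=samples)
    groups = pd.Series([group_a] * n_a + [group_b] * n_b, index=samples, name="group")
    return ExpressionMatrix(values, groups)


def simulate_expression_matrices(
    truth: SyntheticTruth,
    n_a: int = 6,
    n_b: int = 8,
    noise_sd: float = 0.25,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Transcript- and protein-level matrices targeting one paired-LFC draw.

    The default 6 vs. 8 group sizes mirror a small proteomic tumour cohort.
    """
    transcripts, proteins, _ = simulate_paired_lfc(truth)
    rng = truth.rng_for("expression")
    mt = simulate_expression_matrix(
        transcripts.set_index("feature_id")["lfc"], n_a, n_b, noise_sd, rng
    )
    mp = simulate_expression_matrix(
        proteins.set_index("feature_id")["lfc"], n_a, n_b, noise_sd, rng
    )
    return mt, mp


def simulate_gene_sets(
    universe,
    n_sets: int = 30,
    set_size_range: tuple[int, int] = (15, 60),
    planted_members=None,
    planted_set_name: str = "PLANTED_CONCORDANT_UP",
    seed=None,
) -> GeneSetCollection:
    """Random gene sets plus one planted set.

    Random sets are uniform draws from the universe; the planted set (when
    ``planted_members`` is given) consists of genes that received positive
    shifts at both levels, so it should rank at the top of both enrichment
    analyses.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    universe = np.asarray(list(universe), dtype=object)
    lo, hi = set_size_range
    if hi > universe.size:
        raise ValueError("set sizes exceed universe size")
    sets: dict[str, tuple[str, ...]] = {}
    if planted_members is not None:
        sets[planted_set_name] = tuple(sorted(planted_members))
    width = len(str(max(n_sets, 1)))
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=size, replace=False)
        sets[f"RANDOM_SET_{i + 1:0{width}d}"] = tuple(sorted(members))
    return GeneSetCollection(sets, source="synthetic")


def simulate_reference_sets(
    truth: SyntheticTruth,
    drug_fraction: float = 0.5,
    n_decoy_drug_genes: int = 50,
    max_drugs_per_gene: int = 3,
) -> tuple[ReferenceSet, pd.DataFrame]:
    """Plasma membership list and drug-interaction table around the truth.

    The plasma reference contains the planted plasma-flagged discordant genes
    plus out-of-universe decoy identifiers padding it to the nominal source
    size (a plasma atlas mostly lists proteins absent from any one tumour
    panel).  The drug table links a fraction of the planted concordant-up
    genes, plus random background genes, to fake approved drug names.
    """
    rng = truth.rng_for("references")
    n_decoys = truth.plasma_source_size - len(truth.plasma_planted)
    if n_decoys < 0:
        raise ValueError("plasma_source_size smaller than planted plasma membership")
    decoys = [f"PLASMA_DECOY_{i:04d}" for i in range(n_decoys)]
    plasma = ReferenceSet(
        name="plasma_proteome",
        members=frozenset(truth.plasma_planted) | frozenset(decoys),
        source_size=truth.plasma_source_size,
    )

    up = np.asarray(truth.planted_concordant_up, dtype=object)
    n_linked = int(round(drug_fraction * up.size))
    linked = sorted(rng.choice(up, size=n_linked, replace=False))
    planted_all = set(truth.planted_concordant_up) | set(truth.planted_concordant_down) | set(
        truth.planted_discordant
    )
    background = np.asarray(
        [g for g in truth.gene_ids if g not in planted_all], dtype=object
    )
    decoy_genes = sorted(
        rng.choice(background, size=min(n_decoy_drug_genes, background.size), replace=False)
    )
    rows = []
    counter = 0
    for gene in [*linked, *decoy_genes]:
        for _ in range(int(rng.integers(1, max_drugs_per_gene + 1))):
            rows.append({"gene_id": gene, "drug_name": f"DRUG_{counter:04d}", "approved": True})
            counter += 1
    drugs = pd.DataFrame(rows, columns=["gene_id", "drug_name", "approved"])
    return plasma, drugs


def simulate_study(
    truth: SyntheticTruth,
    out_dir,
    n_sets: int = 30,
    set_size_range: tuple[int, int] = (15, 60),
    expr_groups: tuple[int, int] = (6, 8),
    noise_sd: float = 0.25,
    drug_fraction: float = 0.5,
) -> dict:
    """Write a complete synthetic study to ``out_dir``; returns file paths.

    Files: transcripts.tsv, proteins.tsv, expr_t.tsv / expr_t_groups.tsv,
    expr_p.tsv / expr_p_groups.tsv, sets.gmt, plasma.tsv, dgidb.tsv,
    truth.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    transcripts, proteins, truth = simulate_paired_lfc(truth)
    mt, mp = simulate_expression_matrices(truth, *expr_groups, noise_sd=noise_sd)
    sets = simulate_gene_sets(
        truth.gene_ids,
        n_sets=n_sets,
        set_size_range=set_size_range,
        planted_members=truth.planted_concordant_up,
        planted_set_name=truth.planted_set_name,
        seed=truth.rng_for("gene_sets"),
    )
    plasma, drugs = simulate_reference_sets(truth, drug_fraction=drug_fraction)

    paths = {name: out / fname for name, fname in [
        ("transcripts", "transcripts.tsv"), ("proteins", "proteins.tsv"),
        ("expr_t", "expr_t.tsv"), ("expr_t_groups", "expr_t_groups.tsv"),
        ("expr_p", "expr_p.tsv"), ("expr_p_groups", "expr_p_groups.tsv"),
        ("gene_sets", "sets.gmt"), ("plasma", "plasma.tsv"),
        ("drugs", "dgidb.tsv"), ("truth", "truth.json"),
    ]}
    transcripts.to_csv(paths["transcripts"], sep="\t", index=False, float_format=_FLOAT_FMT)
    proteins.to_csv(paths["proteins"], sep="\t", index=False, float_format=_FLOAT_FMT)
    for key, m in (("expr_t", mt), ("expr_p", mp)):
        m.values.rename_axis("feature_id").to_csv(paths[key], sep="\t", float_format=_FLOAT_FMT)
        m.groups.rename_axis("sample").to_csv(paths[f"{key}_groups"], sep="\t")
    write_gmt(sets, paths["gene_sets"])
    pd.DataFrame({"gene_id": sorted(plasma.members)}).to_csv(
        paths["plasma"], sep="\t", index=False
    )
    drugs.to_csv(paths["drugs"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {k: str(v) for k, v in paths.items()}
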