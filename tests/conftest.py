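import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_integrated(lfc_t, lfc_p, gene_ids=None) -> pd.DataFrame:
    """Integrated paired-LFC table from two vectors."""
    n = len(lfc_t)
    if gene_ids is None:
        gene_ids = [f"G{i:04d}" for i in range(n)]
    return pd.DataFrame(
        {"gene_id": gene_ids, "lfc_transcript": lfc_t, "lfc_protein": lfc_p}
    )


def random_tie_free_table(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Random integrated table with (almost surely) tie-free continuous LFCs."""
    return make_integrated(rng.standard_normal(n), rng.standard_normal(n))


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def toy5():
    """5-gene toy with perfectly concordant orderings at both levels."""
    return make_integrated([2.0, 1.0, 0.0, -1.0, -2.0], [3.0, 1.0, 0.0, -1.0, -3.0],
                           gene_ids=list("ABCDE"))


@pytest.fixture(scope="session")
def default_truth():
    from concordia import SyntheticTruth

    return SyntheticTruth(seed=1)


@pytest.fixture(scope="session")
def default_study(default_truth):
    """One default synthetic study, ranked: (truth, transcripts, proteins, ranked)."""
    from concordia import intersect_levels, rank_table, simulate_paired_lfc

    t, p, truth = simulate_paired_lfc(default_truth)
    integrated = intersect_levels(
        t.assign(gene_id=t["feature_id"]), p.assign(gene_id=p["feature_id"])
    )
    return truth, t, p, rank_table(integrated)
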