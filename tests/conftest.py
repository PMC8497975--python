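import numpy as np
import pandas as pd
import pytest

from darscale.io_tables import RANKS, AbundanceTable
from darscale.synthetic import CohortSpec, generate_cohort


def make_tiny_table() -> AbundanceTable:
    """3 samples x 4 genus-level taxa, two genera sharing a family."""
    data = pd.DataFrame(
        [[3.0, 5.0, 0.0, 2.0], [1.0, 0.0, 4.0, 4.0], [0.0, 2.0, 2.0, 6.0]],
        index=["s1", "s2", "s3"],
        columns=["gA", "gB", "gC", "gD"],
    )
    lineages = pd.DataFrame(
        [
            ("P1", "C1", "O1", "F1", "gA"),
            ("P1", "C1", "O1", "F1", "gB"),
            ("P1", "C2", "O2", "F2", "gC"),
            ("P2", "C3", "O3", "F3", "gD"),
        ],
        index=data.columns,
        columns=list(RANKS),
    )
    metadata = pd.DataFrame(
        {"subject_id": ["u1", "u2", "u3"], "site": ["Stool", "Stool", "BM"]},
        index=data.index,
    )
    return AbundanceTable(data=data, lineages=lineages, metadata=metadata)


@pytest.fixture
def tiny_table() -> AbundanceTable:
    return make_tiny_table()


@pytest.fixture(scope="session")
def small_cohort() -> AbundanceTable:
    """10-site cohort with differentiated pools, desk-scale."""
    spec = CohortSpec(
        n_subjects=12,
        pool_size=80,
        pool_overlap=0.3,
        taxonomy_counts=(10, 20, 40, 80, 300),
        seed=7,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def single_site_cohort() -> AbundanceTable:
    """One site, 40 subjects; occupancy in the genus-level scaling regime."""
    spec = CohortSpec(
        n_subjects=40,
        sites=("SiteA",),
        pool_size=200,
        taxonomy_counts=(12, 24, 48, 96, 200),
        occupancy_beta=(1.0, 4.0),
        seed=13,
    )
    return generate_cohort(spec)


def replicated_sample_table(n_subjects: int = 6) -> AbundanceTable:
    """Every sample at every site is one identical community (no accrual)."""
    base = make_tiny_table()
    row = base.data.iloc[0].to_numpy()
    sites = ["BM", "KG", "HP", "TD", "PT", "Th", "Sal", "SupP", "SubP", "Stool"]
    ids, rows, meta = [], [], []
    for site in sites:
        for i in range(n_subjects):
            ids.append(f"u{i}_{site}")
            rows.append(row)
            meta.append((f"u{i}", site))
    data = pd.DataFrame(np.array(rows), index=ids, columns=base.data.columns)
    metadata = pd.DataFrame(meta, index=ids, columns=["subject_id", "site"])
    return AbundanceTable(
        data=data, lineages=base.lineages.copy(), metadata=metadata
    )
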