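import numpy as np
import pytest

from adrpair.model import AdrPairModel
from adrpair.synthetic import GeneratorConfig, generate


@pytest.fixture(scope="session")
def fixture_data():
    """The default 40-drug, 3-ADR noise-free fixture."""
    return generate(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def fixture_model(fixture_data):
    d = fixture_data
    return AdrPairModel.from_tables(
        d.feature_tables, d.drug_gene, d.drug_disease, d.disease_gene, d.ddaa,
        pcn=10, seed=11,
    )


def random_network(rng: np.random.Generator, max_drugs=10, max_diseases=8, max_genes=15):
    """A small random tripartite network for oracle cross-checks."""
    from adrpair.io import TripartiteNetwork

    n_r = rng.integers(2, max_drugs + 1)
    n_d = rng.integers(1, max_diseases + 1)
    n_g = rng.integers(1, max_genes + 1)
    drugs = [f"R{i}" for i in range(n_r)]
    diseases = [f"D{i}" for i in range(n_d)]
    genes = [f"G{i}" for i in range(n_g)]

    def random_sets(owners, pool, p):
        out = {}
        for o in owners:
            chosen = [x for x in pool if rng.random() < p]
            if chosen:
                out[o] = frozenset(chosen)
        return out

    return TripartiteNetwork(
        drugs=set(drugs),
        diseases=set(diseases),
        genes=set(genes),
        drug_genes=random_sets(drugs, genes, 0.3),
        drug_diseases=random_sets(drugs, diseases, 0.3),
        disease_genes=random_sets(diseases, genes, 0.3),
    )


def brute_force_score(a: str, b: str, network) -> dict:
    """Independent nested-loop reference for the interaction score.

    Deliberately naive: explicit element loops over Python sets, no shared
    code with the package's vectorised or set-algebra implementations.
    """
    g1 = network.drug_genes.get(a, frozenset())
    g2 = network.drug_genes.get(b, frozenset())
    d1 = network.drug_diseases.get(a, frozenset())
    d2 = network.drug_diseases.get(b, frozenset())

    shared_genes = [g for g in g1 if g in g2]
    union_genes = list(g1) + [g for g in g2 if g not in g1]
    s_g = len(shared_genes) / len(union_genes) if union_genes else 0.0

    shared_dis = [d for d in d1 if d in d2]
    union_dis = list(d1) + [d for d in d2 if d not in d1]
    n_vd = len(network.diseases)
    s_d = (
        (len(shared_dis) / len(union_dis)) * (len(shared_dis) / n_vd)
        if union_dis
        else 0.0
    )

    covered = []
    for dis in shared_dis:
        for g in network.disease_genes.get(dis, frozenset()):
            if g in shared_genes and g not in covered:
                covered.append(g)
    s_gd = len(covered) / len(shared_genes) if shared_genes and shared_dis else 0.0

    return {
        "inter_g": s_g,
        "inter_d": s_d,
        "inter_gd": s_gd,
        "inter_score": s_g + s_d + s_gd,
    }
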