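"""Self-contained synthetic fixtures: drugs, diseases, genes, feature
tables, tripartite edges and drug-drug-ADR triples with planted structure.

The generator emulates the premises behind credible-negative selection:
interacting drugs share target genes, share associated diseases, and their
shared genes overlap the gene sets of their shared diseases.  Drugs are
organised into per-ADR *communities*: every community member carries the
community's shared gene set and disease set (so all within-community pairs
are planted interacting pairs with a positive tripartite score), each
shared disease's gene set contains the shared genes (so the gene-disease
bridge component is maximal), and every other drug draws genes, diseases
and features from private, disjoint blocks (so non-planted pairs score
exactly zero when noise is off).

Each ADR's positive pairs are a sample of its community's pairs, and every
community drug carries the ADR's signature feature bits at rate
``signal_strength`` — that is the classification signal.  ``noise_rate``
adds (never removes) random association edges and feature bits, so the
planted guarantees survive noising while exact zero scores do not.

It does not attempt to mimic real DrugBank/CTD marginal distributions
beyond sparsity levels, nor drug-level covariate shift between ADRs; a
clean pass here shows the machinery recovers planted structure, not that
real-data performance will match.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .io import (
    FEATURE_NAMESPACES,
    DrugCatalog,
    TripartiteNetwork,
    build_catalog,
    canonical_pair,
    write_association_table,
)


class ConfigError(ValueError):
    """The generator configuration is infeasible."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic fixture.

    Defaults give the 40-drug, 3-ADR benchmark fixture: three interacting
    communities of 12 drugs (198 planted pairs), 10 positive pairs per ADR,
    strong feature signal and no noise.
    """

    n_drugs: int = 40
    n_adrs: int = 3
    community_size: int = 12
    n_interacting_pairs: int | None = None  # if set, community sizes are solved from it
    positives_per_adr: int = 10
    signal_strength: float = 0.9
    noise_rate: float = 0.0
    seed: int = 0
    # tripartite sparsity
    private_genes_per_drug: int = 3
    shared_genes_per_community: int = 2
    private_diseases_per_drug: int = 2
    shared_diseases_per_community: int = 2
    genes_per_private_disease: int = 2
    n_genes: int | None = None  # None: smallest feasible pool
    n_diseases: int | None = None
    # feature-table sparsity (pool size, baseline features per drug, signature size per ADR)
    feature_pools: dict = field(
        default_factory=lambda: {
            "substructure": (50, 6, 4),
            "target": (80, 8, 4),
            "substituent": (30, 4, 3),
            "pathway": (40, 5, 3),
        }
    )

    def __post_init__(self) -> None:
        for name in ("n_drugs", "n_adrs", "community_size", "positives_per_adr"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ConfigError("signal_strength must be in [0, 1]")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ConfigError("noise_rate must be in [0, 1]")


@dataclass
class GroundTruth:
    """What the generator planted."""

    interacting_pairs: set[tuple[str, str]]
    adr_positive_pairs: dict[str, set[tuple[str, str]]]
    adr_signatures: dict[str, dict[str, set[str]]]
    communities: dict[str, list[str]]

    def __post_init__(self) -> None:
        for adr, pos in self.adr_positive_pairs.items():
            if not pos <= self.interacting_pairs:
                raise ValueError(f"{adr}: positives not a subset of planted pairs")

    def to_json(self) -> str:
        return json.dumps(
            {
                "interacting_pairs": sorted(map(list, self.interacting_pairs)),
                "adr_positive_pairs": {
                    a: sorted(map(list, p)) for a, p in self.adr_positive_pairs.items()
                },
                "adr_signatures": {
                    a: {ns: sorted(s) for ns, s in sigs.items()}
                    for a, sigs in self.adr_signatures.items()
                },
                "communities": self.communities,
            },
            indent=2,
            sort_keys=True,
        )


@dataclass
class SyntheticData:
    """All generated tables plus the planted ground truth."""

    feature_tables: dict[str, pd.DataFrame]
    drug_gene: pd.DataFrame
    drug_disease: pd.DataFrame
    disease_gene: pd.DataFrame
    ddaa: pd.DataFrame
    truth: GroundTruth
    config: GeneratorConfig

    def catalog(self) -> DrugCatalog:
        return build_catalog(
            self.feature_tables,
            drug_gene=self.drug_gene,
            drug_disease=self.drug_disease,
            extra_drugs=self.all_drug_ids(),
        )

    def network(self) -> TripartiteNetwork:
        return TripartiteNetwork.from_tables(
            self.drug_gene, self.drug_disease, self.disease_gene,
            extra_drugs=self.all_drug_ids(),
        )

    def all_drug_ids(self) -> list[str]:
        return [f"R{i:04d}" for i in range(self.config.n_drugs)]

    def write(self, outdir: str | Path) -> dict[str, str]:
        """Write every table as CSV plus the ground truth JSON; returns paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for ns, table in self.feature_tables.items():
            p = outdir / f"drug_{ns}.csv"
            write_association_table(table, p)
            paths[ns] = str(p)
        for name, table in [
            ("drug_gene", self.drug_gene),
            ("drug_disease", self.drug_disease),
            ("disease_gene", self.disease_gene),
            ("ddaa", self.ddaa),
        ]:
            p = outdir / f"{name}.csv"
            write_association_table(table, p)
            paths[name] = str(p)
        truth_path = outdir / "ground_truth.json"
        truth_path.write_text(self.truth.to_json() + "\n")
        paths["ground_truth"] = str(truth_path)
        return paths


def _solve_community_sizes(n_pairs: int, n_communities: int) -> list[int]:
    """Community sizes whose within-community pair counts sum to n_pairs.

    Sizes may differ by at most the remainder spread; a leftover that no
    size adjustment can absorb is taken up by standalone planted pairs
    (communities of size 2 contribute one pair each).
    """
    sizes = [2] * n_communities  # each community needs >= 1 pair
    def total(szs: Iterable[int]) -> int:
        return sum(c * (c - 1) // 2 for c in szs)

    if n_pairs < n_communities:
        raise ConfigError(
            f"n_interacting_pairs={n_pairs} cannot host {n_communities} communities"
        )
    # grow communities round-robin while the next increment still fits
    grew = True
    while grew:
        grew = False
        for i in range(n_communities):
            if total(sizes) + sizes[i] <= n_pairs:  # adding one member adds `size` pairs
                sizes[i] += 1
                grew = True
    extra_pairs = n_pairs - total(sizes)
    return sizes + [2] * extra_pairs


def generate(config: GeneratorConfig) -> SyntheticData:
    """Generate all input tables plus ground truth; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    c = config
    drug_ids = [f"R{i:04d}" for i in range(c.n_drugs)]

    if c.n_interacting_pairs is not None:
        sizes = _solve_community_sizes(c.n_interacting_pairs, c.n_adrs)
    else:
        sizes = [c.community_size] * c.n_adrs
    if sum(sizes) > c.n_drugs:
        raise ConfigError(
            f"communities need {sum(sizes)} drugs but n_drugs={c.n_drugs}"
        )
    for k in range(c.n_adrs):
        if c.positives_per_adr > sizes[k] * (sizes[k] - 1) // 2:
            raise ConfigError(
                f"positives_per_adr={c.positives_per_adr} exceeds the "
                f"{sizes[k] * (sizes[k] - 1) // 2} pairs of a size-{sizes[k]} community"
            )

    # community membership decoupled from lexicographic drug order
    shuffled = list(rng.permutation(drug_ids))
    communities: list[list[str]] = []
    cursor = 0
    for sz in sizes:
        communities.append(sorted(shuffled[cursor : cursor + sz]))
        cursor += sz

    # ---- tripartite structure -------------------------------------------
    n_groups = len(sizes)
    need_genes = (
        c.n_drugs * c.private_genes_per_drug + n_groups * c.shared_genes_per_community
    )
    need_dis = (
        c.n_drugs * c.private_diseases_per_drug
        + n_groups * c.shared_diseases_per_community
    )
    n_genes = need_genes if c.n_genes is None else c.n_genes
    n_diseases = need_dis if c.n_diseases is None else c.n_diseases
    if n_genes < need_genes or n_diseases < need_dis:
        raise ConfigError(
            f"pools too small: need {need_genes} genes and {need_dis} diseases"
        )
    genes = [f"G{i:05d}" for i in range(n_genes)]
    diseases = [f"D{i:05d}" for i in range(n_diseases)]
    gene_blocks = iter(rng.permutation(genes))
    dis_blocks = iter(rng.permutation(diseases))

    def take(it, n):
        return [next(it) for _ in range(n)]

    drug_genes: dict[str, set[str]] = {d: set(take(gene_blocks, c.private_genes_per_drug)) for d in drug_ids}
    drug_dis: dict[str, set[str]] = {d: set(take(dis_blocks, c.private_diseases_per_drug)) for d in drug_ids}
    disease_genes: dict[str, set[str]] = {}
    # private diseases draw their gene sets from the owner's private genes
    for d in drug_ids:
        private = sorted(drug_genes[d])
        for dis in sorted(drug_dis[d]):
            k = min(c.genes_per_private_disease, len(private))
            disease_genes[dis] = set(rng.choice(private, size=k, replace=False))

    interacting: set[tuple[str, str]] = set()
    for members in communities:
        shared_g = set(take(gene_blocks, c.shared_genes_per_community))
        shared_d = set(take(dis_blocks, c.shared_diseases_per_community))
        for d in members:
            drug_genes[d] |= shared_g
            drug_dis[d] |= shared_d
        for dis in shared_d:
            # bridge premise: shared genes belong to the shared diseases' gene sets
            disease_genes[dis] = set(shared_g)
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                interacting.add(canonical_pair(a, b))

    # ---- ADR positives & signatures -------------------------------------
    adr_ids = [f"ADR{k:03d}" for k in range(c.n_adrs)]
    adr_positives: dict[str, set[tuple[str, str]]] = {}
    for k, adr in enumerate(adr_ids):
        members = communities[k]
        pairs = sorted(
            canonical_pair(a, b)
            for i, a in enumerate(members)
            for b in members[i + 1 :]
        )
        chosen = rng.choice(len(pairs), size=c.positives_per_adr, replace=False)
        adr_positives[adr] = {pairs[i] for i in sorted(chosen)}

    pool_features = {
        ns: [f"{ns[:4].upper()}{i:05d}" for i in range(c.feature_pools[ns][0])]
        for ns in FEATURE_NAMESPACES
    }
    # signatures disjoint across ADRs within each namespace
    signatures: dict[str, dict[str, set[str]]] = {a: {} for a in adr_ids}
    for ns in FEATURE_NAMESPACES:
        pool, _, sig_size = c.feature_pools[ns]
        if c.n_adrs * sig_size > pool:
            raise ConfigError(f"{ns}: pool {pool} too small for {c.n_adrs} signatures")
        perm = list(rng.permutation(pool_features[ns]))
        for k, adr in enumerate(adr_ids):
            signatures[adr][ns] = set(perm[k * sig_size : (k + 1) * sig_size])

    drug_features: dict[str, dict[str, set[str]]] = {
        d: {ns: set() for ns in FEATURE_NAMESPACES} for d in drug_ids
    }
    for ns in FEATURE_NAMESPACES:
        _, baseline, _ = c.feature_pools[ns]
        for d in drug_ids:
            drug_features[d][ns] = set(
                rng.choice(pool_features[ns], size=baseline, replace=False)
            )
    for k, adr in enumerate(adr_ids):
        for d in communities[k]:
            for ns in FEATURE_NAMESPACES:
                for feat in sorted(signatures[adr][ns]):
                    if rng.random() < c.signal_strength:
                        drug_features[d][ns].add(feat)

    # ---- additive noise (never removes planted bits/edges) --------------
    if c.noise_rate > 0:
        for d in drug_ids:
            drug_genes[d] |= {g for g in genes if rng.random() < c.noise_rate}
            drug_dis[d] |= {x for x in diseases if rng.random() < c.noise_rate}
            for ns in FEATURE_NAMESPACES:
                drug_features[d][ns] |= {
                    f for f in pool_features[ns] if rng.random() < c.noise_rate
                }

    # ---- assemble tables -------------------------------------------------
    def assoc(mapping: dict[str, set[str]], left: str, right: str) -> pd.DataFrame:
        rows = [(k, v) for k in sorted(mapping) for v in sorted(mapping[k])]
        return pd.DataFrame(rows, columns=[left, right])

    feature_tables = {
        ns: pd.DataFrame(
            [(d, f) for d in drug_ids for f in sorted(drug_features[d][ns])],
            columns=["drug", ns],
        )
        for ns in FEATURE_NAMESPACES
    }
    ddaa = pd.DataFrame(
        [(a, b, adr) for adr in adr_ids for a, b in sorted(adr_positives[adr])],
        columns=["drug_a", "drug_b", "adr"],
    )
    truth = GroundTruth(
        interacting_pairs=interacting,
        adr_positive_pairs=adr_positives,
        adr_signatures=signatures,
        communities={adr_ids[k]: communities[k] for k in range(c.n_adrs)},
    )
    return SyntheticData(
        feature_tables=feature_tables,
        drug_gene=assoc(drug_genes, "drug", "gene"),
        drug_disease=assoc(drug_dis, "drug", "disease"),
        disease_gene=assoc({k: v for k, v in disease_genes.items() if v}, "disease", "gene"),
        ddaa=ddaa,
        truth=truth,
        config=c,
    )


def expected_separation(config: GeneratorConfig) -> float:
    """Analytic lower bound on the interaction-score gap between planted
    and non-planted pairs, valid only for noise-free configurations where
    non-planted pairs score exactly zero.

    A planted pair shares the community's s genes on top of 2p disjoint
    private genes (gene component >= s/(s+2p)), shares t of the realised
    disease universe (disease component >= (t/(t+2q)) * (t/|V_d|)), and the
    shared diseases' gene sets contain all shared genes (bridge = 1).
    """
    c = config
    if c.noise_rate != 0:
        raise ValueError("analytic bound requires noise_rate = 0; use Monte-Carlo")
    if c.n_interacting_pairs is not None:
        sizes = _solve_community_sizes(c.n_interacting_pairs, c.n_adrs)
    else:
        sizes = [c.community_size] * c.n_adrs
    s = c.shared_genes_per_community
    t = c.shared_diseases_per_community
    p = c.private_genes_per_drug
    q = c.private_diseases_per_drug
    realized_diseases = c.n_drugs * q + len(sizes) * t
    if c.n_diseases is not None:
        realized_diseases = min(realized_diseases, c.n_diseases)
    gap = s / (s + 2 * p) + (t / (t + 2 * q)) * (t / realized_diseases) + 1.0
    return gap
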