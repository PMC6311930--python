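"""Tripartite drug-disease-gene interaction scoring and credible negative
pair selection.

Pairs of drugs that are likely to interact tend to (i) share target genes,
(ii) treat overlapping disease sets, and (iii) have shared genes that are
also genes of their shared diseases.  Each candidate pair gets three
component scores in [0, 1]:

* ``inter_g``  — Jaccard index of the two drugs' gene sets,
* ``inter_d``  — Jaccard index of the disease sets, damped by the fraction
  of all network diseases the pair shares,
* ``inter_gd`` — fraction of the shared genes that belong to the gene set
  of at least one shared disease,

and a total ``inter_score`` in [0, 3], their exact sum.  Ranking all
candidate pairs ascending by total score puts the pairs least likely to
interact first; the prefix of that ranking (minus an ADR's known positive
pairs) supplies highly-credible negative training samples.

All ratios are cardinality ratios; every 0/0 case is defined as 0, the
conservative "no evidence of interaction" value for a procedure that
treats low scores as negatives.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import AbstractSet, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import TripartiteNetwork, canonical_pair


@dataclass(frozen=True)
class PairScore:
    """Interaction-score components for one canonical drug pair."""

    drug_a: str
    drug_b: str
    inter_g: float
    inter_d: float
    inter_gd: float

    @property
    def inter_score(self) -> float:
        return self.inter_g + self.inter_d + self.inter_gd


class CapacityError(ValueError):
    """Not enough non-positive candidate pairs to fill a negative set."""


def inter_g(g1: AbstractSet[str], g2: AbstractSet[str]) -> float:
    """Gene-overlap component: |G1 n G2| / |G1 u G2| (0 if both empty)."""
    union = len(g1 | g2)
    if union == 0:
        return 0.0
    return len(g1 & g2) / union


def inter_d(d1: AbstractSet[str], d2: AbstractSet[str], n_diseases: int) -> float:
    """Disease-therapeutic component.

    Jaccard overlap of the two disease sets, multiplied by the shared
    diseases as a fraction of all ``n_diseases`` diseases in the network:
    (|D1 n D2| / |D1 u D2|) * (|D1 n D2| / |V_d|).  Zero when the union is
    empty.
    """
    if n_diseases < 1:
        raise ValueError("network has no diseases; inter_d is undefined")
    union = len(d1 | d2)
    if union == 0:
        return 0.0
    shared = len(d1 & d2)
    return (shared / union) * (shared / n_diseases)


def inter_gd(
    g1: AbstractSet[str],
    g2: AbstractSet[str],
    shared_disease_genes: Sequence[AbstractSet[str]],
) -> float:
    """Gene-disease-bridge component.

    Of the genes shared by the two drugs, the fraction that belongs to the
    gene set of at least one disease the drugs also share:
    |union_k ((G1 n G2) n DG_k)| / |G1 n G2|.  Zero when the drugs share no
    genes or no diseases.
    """
    shared_genes = g1 & g2
    if not shared_genes or not shared_disease_genes:
        return 0.0
    covered: set[str] = set()
    for dg in shared_disease_genes:
        covered |= shared_genes & dg
    return len(covered) / len(shared_genes)


def score_pair(a: str, b: str, network: TripartiteNetwork) -> PairScore:
    """Score one drug pair against the tripartite network (Eqs. of the
    component docstrings); components computed from the network's
    drug-gene, drug-disease and disease-gene edges."""
    a, b = canonical_pair(a, b)
    g1, g2 = network.genes_of(a), network.genes_of(b)
    d1, d2 = network.diseases_of(a), network.diseases_of(b)
    shared_d = d1 & d2
    dg_sets = [network.genes_of_disease(k) for k in shared_d]
    return PairScore(
        drug_a=a,
        drug_b=b,
        inter_g=inter_g(g1, g2),
        inter_d=inter_d(d1, d2, len(network.diseases)),
        inter_gd=inter_gd(g1, g2, dg_sets),
    )


def _membership_matrix(
    row_ids: Sequence[str], sets: dict[str, frozenset[str]], col_index: dict[str, int]
) -> sp.csr_matrix:
    rows, cols = [], []
    for i, rid in enumerate(row_ids):
        for item in sets.get(rid, ()):
            rows.append(i)
            cols.append(col_index[item])
    data = np.ones(len(rows), dtype=np.int32)
    return sp.csr_matrix(
        (data, (rows, cols)), shape=(len(row_ids), len(col_index)), dtype=np.int32
    )


def score_all_pairs(network: TripartiteNetwork) -> pd.DataFrame:
    """Score every canonical drug pair in the network.

    Vectorised: pairwise gene/disease intersection counts come from sparse
    matrix products; the bridge component only needs per-pair set work for
    pairs that share both a gene and a disease, which real association data
    keeps sparse.

    Returns a DataFrame with columns drug_a, drug_b, inter_g, inter_d,
    inter_gd, inter_score, one row per unordered pair (unsorted).
    """
    drugs = sorted(network.drugs)
    n = len(drugs)
    if n < 2:
        raise ValueError("need at least 2 drugs to enumerate pairs")
    gene_ix = {g: i for i, g in enumerate(sorted(network.genes))}
    dis_ix = {d: i for i, d in enumerate(sorted(network.diseases))}

    Mg = _membership_matrix(drugs, network.drug_genes, gene_ix)
    Md = _membership_matrix(drugs, network.drug_diseases, dis_ix)

    GI = np.asarray((Mg @ Mg.T).todense())
    DI = np.asarray((Md @ Md.T).todense())
    gdeg = np.asarray(Mg.sum(axis=1)).ravel()
    ddeg = np.asarray(Md.sum(axis=1)).ravel()

    iu, ju = np.triu_indices(n, k=1)
    gi = GI[iu, ju].astype(np.float64)
    di = DI[iu, ju].astype(np.float64)
    gu = gdeg[iu] + gdeg[ju] - gi
    du = ddeg[iu] + ddeg[ju] - di

    with np.errstate(divide="ignore", invalid="ignore"):
        s_g = np.where(gu > 0, gi / gu, 0.0)
        s_d = np.where(du > 0, (di / du) * (di / max(len(network.diseases), 1)), 0.0)
    if len(network.diseases) == 0 and du.max(initial=0) > 0:
        raise ValueError("network has no diseases; inter_d is undefined")

    s_gd = np.zeros(len(iu))
    # bridge component: only pairs sharing >=1 gene and >=1 disease
    need = np.flatnonzero((gi > 0) & (di > 0))
    gsets = {d: network.drug_genes.get(d, frozenset()) for d in drugs}
    dsets = {d: network.drug_diseases.get(d, frozenset()) for d in drugs}
    for k in need:
        a, b = drugs[iu[k]], drugs[ju[k]]
        shared_genes = gsets[a] & gsets[b]
        covered: set[str] = set()
        for dis in dsets[a] & dsets[b]:
            covered |= shared_genes & network.genes_of_disease(dis)
        s_gd[k] = len(covered) / len(shared_genes)

    return pd.DataFrame(
        {
            "drug_a": [drugs[i] for i in iu],
            "drug_b": [drugs[j] for j in ju],
            "inter_g": s_g,
            "inter_d": s_d,
            "inter_gd": s_gd,
            "inter_score": s_g + s_d + s_gd,
        }
    )


def rank_pairs(network: TripartiteNetwork) -> pd.DataFrame:
    """Score and rank all candidate pairs ascending by ``inter_score``.

    Ties are broken by the canonical pair ID, so the ranking is
    deterministic regardless of input order.  For n drugs the result has
    n(n-1)/2 rows; pairs low in the list are the least likely to interact
    and are the credible-negative candidates.
    """
    scores = score_all_pairs(network)
    return scores.sort_values(
        ["inter_score", "drug_a", "drug_b"], kind="mergesort", ignore_index=True
    )


def select_negatives(
    ranked: pd.DataFrame,
    positives: AbstractSet[tuple[str, str]],
    nsr: float,
) -> list[tuple[str, str]]:
    """Take the prefix of the ascending ranking, skipping known positives.

    Collects ``round(nsr * |positives|)`` pairs (round-half-to-even).
    Raises :class:`CapacityError` if the ranking runs out first.
    """
    if nsr <= 0:
        raise ValueError("nsr must be positive")
    want = round(nsr * len(positives))
    out: list[tuple[str, str]] = []
    for a, b in zip(ranked["drug_a"], ranked["drug_b"]):
        if len(out) == want:
            break
        if (a, b) in positives:
            continue
        out.append((a, b))
    if len(out) < want:
        raise CapacityError(
            f"needed {want} negative pairs but only {len(out)} candidates available"
        )
    return out


def write_ranked(ranked: pd.DataFrame, path: str | Path) -> None:
    """Write the ranked-pair list as TSV (pair IDs plus four score columns)."""
    ranked.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_ranked(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"drug_a": str, "drug_b": str})
    return df
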