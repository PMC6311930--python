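"""Domain types and delimited-text IO for drug association tables.

All inputs are plain CSV/TSV files with a header row and two ID columns
(e.g. drug/substructure, drug/gene, disease/gene, or drug/drug/ADR
triples).  IDs are opaque, case-sensitive strings; no attempt is made to
resolve DrugBank / MeSH / UMLS semantics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: the four feature namespaces that make up a drug vector, in block order
FEATURE_NAMESPACES = ("substructure", "target", "substituent", "pathway")


class SchemaError(ValueError):
    """A required column is missing from an association table."""


class RowValidationError(ValueError):
    """A row contains an empty or invalid ID field."""


class SelfPairError(ValueError):
    """A drug paired with itself is not a combined medication."""


@dataclass(frozen=True)
class DrugRecord:
    """Per-drug feature sets across the four namespaces plus CTD gene and
    disease association sets used by the interaction scorer."""

    drug_id: str
    substructures: frozenset[str] = frozenset()
    targets: frozenset[str] = frozenset()
    substituents: frozenset[str] = frozenset()
    pathways: frozenset[str] = frozenset()
    ctd_genes: frozenset[str] = frozenset()
    ctd_diseases: frozenset[str] = frozenset()

    def feature_set(self, namespace: str) -> frozenset[str]:
        return {
            "substructure": self.substructures,
            "target": self.targets,
            "substituent": self.substituents,
            "pathway": self.pathways,
        }[namespace]


@dataclass(frozen=True)
class FeatureCatalog:
    """Ordered feature-ID list for one namespace; defines vector columns.

    IDs are sorted lexicographically once at build time so matrices are
    reproducible across runs.
    """

    namespace: str
    feature_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError(f"duplicate feature IDs in namespace {self.namespace!r}")

    def __len__(self) -> int:
        return len(self.feature_ids)

    @property
    def index(self) -> dict[str, int]:
        return {f: i for i, f in enumerate(self.feature_ids)}


@dataclass
class DrugCatalog:
    """All drugs with their feature sets plus the four feature catalogs."""

    drugs: dict[str, DrugRecord]
    catalogs: dict[str, FeatureCatalog]

    @property
    def drug_ids(self) -> list[str]:
        return sorted(self.drugs)

    @property
    def vector_length(self) -> int:
        return sum(len(self.catalogs[ns]) for ns in FEATURE_NAMESPACES)

    def manifest(self) -> dict:
        n = len(self.drugs)
        return {
            "n_drugs": n,
            "n_candidate_pairs": n * (n - 1) // 2,
            "namespace_sizes": {ns: len(self.catalogs[ns]) for ns in FEATURE_NAMESPACES},
            "vector_length": self.vector_length,
        }


@dataclass
class TripartiteNetwork:
    """Drug-disease-gene association network.

    Nodes are three disjoint layers (drugs V_r, diseases V_d, genes V_g);
    edges are unweighted, unordered associations: drug-gene, drug-disease
    and disease-gene.
    """

    drugs: set[str]
    diseases: set[str]
    genes: set[str]
    drug_genes: dict[str, frozenset[str]]
    drug_diseases: dict[str, frozenset[str]]
    disease_genes: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for d, gs in self.drug_genes.items():
            if d not in self.drugs or not gs <= self.genes:
                raise ValueError(f"drug-gene edge endpoint missing from node sets: {d}")
        for d, ds in self.drug_diseases.items():
            if d not in self.drugs or not ds <= self.diseases:
                raise ValueError(f"drug-disease edge endpoint missing from node sets: {d}")
        for k, gs in self.disease_genes.items():
            if k not in self.diseases or not gs <= self.genes:
                raise ValueError(f"disease-gene edge endpoint missing from node sets: {k}")

    def genes_of(self, drug_id: str) -> frozenset[str]:
        if drug_id not in self.drugs:
            raise KeyError(f"unknown drug {drug_id!r}")
        return self.drug_genes.get(drug_id, frozenset())

    def diseases_of(self, drug_id: str) -> frozenset[str]:
        if drug_id not in self.drugs:
            raise KeyError(f"unknown drug {drug_id!r}")
        return self.drug_diseases.get(drug_id, frozenset())

    def genes_of_disease(self, disease_id: str) -> frozenset[str]:
        return self.disease_genes.get(disease_id, frozenset())

    @classmethod
    def from_tables(
        cls,
        drug_gene: pd.DataFrame,
        drug_disease: pd.DataFrame,
        disease_gene: pd.DataFrame,
        extra_drugs: Iterable[str] = (),
    ) -> "TripartiteNetwork":
        """Build the network from three two-column association tables.

        ``extra_drugs`` adds drugs with no gene/disease associations (they
        score zero against every partner) so the candidate pair universe
        can cover a whole catalog.
        """
        dg = _group_sets(drug_gene)
        dd = _group_sets(drug_disease)
        kg = _group_sets(disease_gene)
        drugs = set(dg) | set(dd) | set(extra_drugs)
        diseases = set(kg) | set().union(*dd.values()) if dd else set(kg)
        genes = set().union(*dg.values()) if dg else set()
        genes |= set().union(*kg.values()) if kg else set()
        return cls(
            drugs=drugs,
            diseases=diseases,
            genes=genes,
            drug_genes=dg,
            drug_diseases=dd,
            disease_genes=kg,
        )


def _group_sets(table: pd.DataFrame) -> dict[str, frozenset[str]]:
    left, right = table.columns[:2]
    return {
        str(k): frozenset(map(str, v))
        for k, v in table.groupby(left, sort=False)[right].agg(set).items()
    }


def canonical_pair(drug_id_x: str, drug_id_y: str) -> tuple[str, str]:
    """Order a drug pair canonically (lexicographically smaller ID first).

    Raises
    ------
    SelfPairError
        If both IDs are equal: a drug combined with itself is not a
        pairwise medication.
    """
    if drug_id_x == drug_id_y:
        raise SelfPairError(f"self-pair {drug_id_x!r} is not a combined medication")
    return (drug_id_x, drug_id_y) if drug_id_x < drug_id_y else (drug_id_y, drug_id_x)


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_association_table(
    path: str | Path,
    schema: Mapping[str, str] | Sequence[str] | None = None,
) -> pd.DataFrame:
    """Read a two-or-more-column delimited association table.

    Parameters
    ----------
    path
        CSV or TSV file (dialect auto-detected from the extension) with a
        header row.
    schema
        Either a sequence of column names to extract in order, or a mapping
        of role -> column name whose values are used in order.  ``None``
        keeps all columns.

    Returns
    -------
    pandas.DataFrame
        Deduplicated rows with whitespace-trimmed string IDs, file order
        preserved.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    if schema is not None:
        cols = list(schema.values()) if isinstance(schema, Mapping) else list(schema)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise SchemaError(
                f"{path.name}: missing column(s) {missing}; found {list(df.columns)}"
            )
        df = df[cols]
    for col in df.columns:
        df[col] = df[col].str.strip()
        empty = df.index[df[col] == ""]
        if len(empty):
            # +2: header line plus 1-based numbering
            raise RowValidationError(
                f"{path.name}: empty {col!r} field at line {int(empty[0]) + 2}"
            )
    return df.drop_duplicates(ignore_index=True)


def write_association_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a table in the same dialect :func:`read_association_table` reads."""
    table.to_csv(path, sep=_sep_for(path), index=False)


def read_ddaa_table(path: str | Path) -> pd.DataFrame:
    """Read (drug_a, drug_b, adr) triples, canonicalising pair order and
    dropping duplicate (pair, adr) rows."""
    df = read_association_table(path)
    if df.shape[1] < 3:
        raise SchemaError(f"{Path(path).name}: expected 3 columns (drug, drug, adr)")
    a, b, adr = df.columns[:3]
    pairs = [canonical_pair(x, y) for x, y in zip(df[a], df[b])]
    out = pd.DataFrame(
        {"drug_a": [p[0] for p in pairs], "drug_b": [p[1] for p in pairs], "adr": df[adr]}
    )
    return out.drop_duplicates(ignore_index=True)


def build_catalog(
    feature_tables: Mapping[str, pd.DataFrame],
    drug_gene: pd.DataFrame | None = None,
    drug_disease: pd.DataFrame | None = None,
    extra_drugs: Iterable[str] = (),
) -> DrugCatalog:
    """Assemble a :class:`DrugCatalog` from per-namespace association tables.

    Parameters
    ----------
    feature_tables
        Mapping from namespace name (``substructure``, ``target``,
        ``substituent``, ``pathway``) to a (drug_id, feature_id) table.
        Missing namespaces yield empty catalogs.
    drug_gene, drug_disease
        CTD-style association tables feeding the interaction scorer.
    extra_drugs
        Drug IDs to retain even if absent from every table (e.g. drugs seen
        only in the DDAA triples); they get all-empty feature sets.

    The catalog drug set is the union of drug IDs across all tables; each
    namespace's feature order is the lexicographic sort of the IDs seen.
    """
    unknown = set(feature_tables) - set(FEATURE_NAMESPACES)
    if unknown:
        raise ValueError(f"unknown namespaces {sorted(unknown)}")
    if not any(len(t) for t in feature_tables.values()) and (
        drug_gene is None or not len(drug_gene)
    ) and (drug_disease is None or not len(drug_disease)):
        if not extra_drugs:
            raise ValueError("all input tables are empty")

    per_ns: dict[str, dict[str, frozenset[str]]] = {}
    catalogs: dict[str, FeatureCatalog] = {}
    drug_ids: set[str] = set(extra_drugs)
    for ns in FEATURE_NAMESPACES:
        table = feature_tables.get(ns)
        sets = _group_sets(table) if table is not None and len(table) else {}
        per_ns[ns] = sets
        feats = sorted(set().union(*sets.values())) if sets else []
        catalogs[ns] = FeatureCatalog(namespace=ns, feature_ids=tuple(feats))
        drug_ids |= set(sets)

    gene_sets = _group_sets(drug_gene) if drug_gene is not None and len(drug_gene) else {}
    disease_sets = (
        _group_sets(drug_disease) if drug_disease is not None and len(drug_disease) else {}
    )
    drug_ids |= set(gene_sets) | set(disease_sets)

    no_features = sorted(
        d for d in drug_ids if all(d not in per_ns[ns] for ns in FEATURE_NAMESPACES)
    )
    if no_features:
        logger.warning(
            "%d drug(s) have no feature-table rows (all-zero vectors): %s%s",
            len(no_features),
            ", ".join(no_features[:5]),
            " ..." if len(no_features) > 5 else "",
        )

    drugs = {
        d: DrugRecord(
            drug_id=d,
            substructures=per_ns["substructure"].get(d, frozenset()),
            targets=per_ns["target"].get(d, frozenset()),
            substituents=per_ns["substituent"].get(d, frozenset()),
            pathways=per_ns["pathway"].get(d, frozenset()),
            ctd_genes=gene_sets.get(d, frozenset()),
            ctd_diseases=disease_sets.get(d, frozenset()),
        )
        for d in sorted(drug_ids)
    }
    return DrugCatalog(drugs=drugs, catalogs=catalogs)


def write_manifest(catalog: DrugCatalog, path: str | Path) -> None:
    Path(path).write_text(json.dumps(catalog.manifest(), indent=2, sort_keys=True) + "\n")
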