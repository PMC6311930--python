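"""End-to-end model: credible-negative selection + per-ADR classifiers.

Follows the statsmodels convention: :class:`AdrPairModel` holds the data
(drug catalog, tripartite network, known drug-drug-ADR triples) and the
configuration; ``fit()`` runs the whole procedure — rank candidate pairs by
tripartite interaction score, select per-ADR credible negatives, reduce the
binary pair vectors with PCA inside each training fold, cross-validate one
classifier per ADR — and returns an :class:`AdrPairResults` carrying the
evaluation report, the production classifiers retrained on all data, and a
``summary()`` table.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import featurize, scoring
from .io import DrugCatalog, TripartiteNetwork, canonical_pair, read_association_table, read_ddaa_table, build_catalog
from .prediction import (
    AdrDataset,
    EvalReport,
    cross_validate_adr,
    decision_scores,
    fit_reduce,
    train_classifier,
)

logger = logging.getLogger(__name__)


def _spawn_seeds(seed: int, n: int, salt: str) -> list[int]:
    """Deterministically fan a top-level seed out to n child seeds (< 2**31)."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(abs(hash_stable(salt)),))
    return [int(s) % (2**31) for s in ss.generate_state(n, dtype=np.uint64)]


def hash_stable(text: str) -> int:
    return int.from_bytes(hashlib.sha256(text.encode()).digest()[:4], "big")


@dataclass
class ModelConfig:
    """Tunable parameters of the pipeline.

    nsr
        Negative-sample ratio: negatives per positive for each ADR.
    pcn
        PCA component count for the reduced pair-vector space (clamped per
        training fold to the feasible maximum, with a warning).
    algo
        One of ``svm``, ``logreg``, ``knn``, ``rf``.
    folds
        Cross-validation fold count.
    min_positives
        ADRs with fewer known positive pairs are skipped.
    exclude_all_positives
        If True, negatives avoid every ADR's positives, not just the
        current ADR's.
    """

    nsr: float = 1.0
    pcn: int = 300
    algo: str = "svm"
    folds: int = 5
    seed: int = 0
    min_positives: int = 10
    exclude_all_positives: bool = False

    def to_dict(self) -> dict:
        return {
            "nsr": self.nsr,
            "pcn": self.pcn,
            "algo": self.algo,
            "folds": self.folds,
            "seed": self.seed,
            "min_positives": self.min_positives,
            "exclude_all_positives": self.exclude_all_positives,
        }


class AdrPairModel:
    """Pairwise-medication ADR prediction with credible negative sampling.

    Parameters
    ----------
    catalog
        Drug feature sets and namespace catalogs (defines the binary
        vector encoding).
    network
        Drug-disease-gene association network used to score candidate
        pairs; low-scoring pairs become negative training samples.
    ddaa
        Known (drug_a, drug_b, adr) triples — the positive samples.
    config
        :class:`ModelConfig`; keyword overrides accepted.
    """

    def __init__(
        self,
        catalog: DrugCatalog,
        network: TripartiteNetwork,
        ddaa: pd.DataFrame,
        config: ModelConfig | None = None,
        **overrides,
    ) -> None:
        self.catalog = catalog
        self.network = network
        self.ddaa = ddaa.copy()
        cfg = config or ModelConfig()
        for k, v in overrides.items():
            if not hasattr(cfg, k):
                raise TypeError(f"unknown config key {k!r}")
            setattr(cfg, k, v)
        self.config = cfg
        self._vectors: dict[str, sp.csr_matrix] | None = None
        self._ranked: pd.DataFrame | None = None

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_tables(
        cls,
        feature_tables: Mapping[str, pd.DataFrame],
        drug_gene: pd.DataFrame,
        drug_disease: pd.DataFrame,
        disease_gene: pd.DataFrame,
        ddaa: pd.DataFrame,
        **config,
    ) -> "AdrPairModel":
        extra = sorted(set(ddaa["drug_a"]) | set(ddaa["drug_b"]))
        catalog = build_catalog(
            dict(feature_tables), drug_gene=drug_gene, drug_disease=drug_disease,
            extra_drugs=extra,
        )
        network = TripartiteNetwork.from_tables(
            drug_gene, drug_disease, disease_gene, extra_drugs=catalog.drug_ids
        )
        return cls(catalog, network, ddaa, **config)

    @classmethod
    def from_files(cls, paths: Mapping[str, str | Path], **config) -> "AdrPairModel":
        """Build from a mapping with keys substructure/target/substituent/
        pathway/drug_gene/drug_disease/disease_gene/ddaa."""
        feats = {
            ns: read_association_table(paths[ns])
            for ns in ("substructure", "target", "substituent", "pathway")
            if ns in paths
        }
        return cls.from_tables(
            feats,
            read_association_table(paths["drug_gene"]),
            read_association_table(paths["drug_disease"]),
            read_association_table(paths["disease_gene"]),
            read_ddaa_table(paths["ddaa"]),
            **config,
        )

    # -- shared intermediates -----------------------------------------------

    @property
    def vectors(self) -> dict[str, sp.csr_matrix]:
        if self._vectors is None:
            self._vectors = featurize.encode_all_drugs(self.catalog)
        return self._vectors

    @property
    def ranked_pairs(self) -> pd.DataFrame:
        """All candidate pairs ranked ascending by interaction score."""
        if self._ranked is None:
            self._ranked = scoring.rank_pairs(self.network)
        return self._ranked

    def positives_by_adr(self) -> dict[str, set[tuple[str, str]]]:
        out: dict[str, set[tuple[str, str]]] = {}
        for a, b, adr in zip(self.ddaa["drug_a"], self.ddaa["drug_b"], self.ddaa["adr"]):
            out.setdefault(adr, set()).add(canonical_pair(a, b))
        return out

    def build_adr_dataset(
        self, adr: str, negatives: Sequence[tuple[str, str]] | None = None
    ) -> AdrDataset:
        """Positives from the DDAA table plus negatives (credible-negative
        prefix selection unless an explicit list is supplied)."""
        positives = sorted(self.positives_by_adr()[adr])
        if negatives is None:
            exclude: set[tuple[str, str]] = set(positives)
            if self.config.exclude_all_positives:
                for pos in self.positives_by_adr().values():
                    exclude |= pos
            negatives = scoring.select_negatives(
                self.ranked_pairs, exclude, self.config.nsr
            )
            # the negative count is still nsr * |this ADR's positives|
            negatives = negatives[: round(self.config.nsr * len(positives))]
        pairs = list(positives) + list(negatives)
        labels = np.array([1] * len(positives) + [0] * len(negatives))
        matrix = featurize.build_matrix(pairs, self.vectors)
        return AdrDataset(adr_id=adr, pairs=pairs, labels=labels, matrix=matrix)

    # -- fitting -------------------------------------------------------------

    def fit(self, seed: int | None = None) -> "AdrPairResults":
        """Run negative selection, cross-validated evaluation and final
        (all-data) training for every ADR with enough positives."""
        cfg = self.config
        if seed is not None:
            cfg.seed = seed
        positives = self.positives_by_adr()
        adrs = sorted(a for a, p in positives.items() if len(p) >= cfg.min_positives)
        skipped = sorted(set(positives) - set(adrs))
        if skipped:
            logger.warning(
                "%d ADR(s) below min_positives=%d skipped: %s",
                len(skipped), cfg.min_positives, ", ".join(skipped[:5]),
            )
        if not adrs:
            raise ValueError(
                f"no ADR has >= {cfg.min_positives} positive pairs; nothing to fit"
            )

        per_adr: dict[str, dict] = {}
        fold_assignments: dict[str, list[int]] = {}
        models: dict[str, dict] = {}
        cv_seeds = dict(zip(adrs, _spawn_seeds(cfg.seed, len(adrs), "cv")))
        for adr in adrs:
            ds = self.build_adr_dataset(adr)
            metrics, folds, _, _ = cross_validate_adr(
                ds, cfg.pcn, cfg.algo, cfg.folds, cv_seeds[adr]
            )
            per_adr[adr] = metrics
            fold_assignments[adr] = list(map(int, folds))
            models[adr] = self._fit_full(ds, cv_seeds[adr])

        report = EvalReport(
            per_adr=per_adr, config=cfg.to_dict(), fold_assignments=fold_assignments
        )
        return AdrPairResults(model=self, report=report, adr_models=models)

    def _fit_full(self, ds: AdrDataset, seed: int) -> dict:
        """Production classifier for one ADR: reducer + classifier retrained
        on all of the ADR's labelled pairs."""
        cfg = self.config
        pcn = min(cfg.pcn, ds.matrix.shape[0], ds.matrix.shape[1])
        space = fit_reduce(ds.matrix, pcn, seed=seed)
        clf = train_classifier(space.transform(ds.matrix), ds.labels, cfg.algo, seed=seed)
        return {"space": space, "clf": clf}


@dataclass
class AdrPairResults:
    """Fitted per-ADR classifiers plus the cross-validated evaluation."""

    model: AdrPairModel
    report: EvalReport
    adr_models: dict[str, dict] = field(default_factory=dict)

    @property
    def macro(self) -> dict:
        return self.report.macro

    def predict_adrs(
        self, drug_a: str, drug_b: str, top: int | None = None
    ) -> pd.DataFrame:
        """Score one drug pair against every fitted ADR classifier.

        Returns ADRs sorted by descending prediction score (ties broken by
        ADR ID); ``top`` larger than the model count returns everything.
        """
        a, b = canonical_pair(drug_a, drug_b)
        pair_vec = featurize.encode_pair(a, b, self.model.vectors)
        rows = []
        for adr, parts in self.adr_models.items():
            z = parts["space"].transform(pair_vec)
            rows.append((adr, float(decision_scores(parts["clf"], z)[0])))
        df = pd.DataFrame(rows, columns=["adr", "score"])
        df = df.sort_values(
            ["score", "adr"], ascending=[False, True], ignore_index=True
        )
        return df.head(top) if top is not None else df

    def summary(self) -> str:
        """Human-readable per-ADR + macro metric table."""
        frame = self.report.to_frame()
        cfg = self.report.config
        header = (
            "Pairwise-medication ADR prediction (credible negative sampling)\n"
            f"classifier={cfg.get('algo')}  nsr={cfg.get('nsr')}  "
            f"pcn={cfg.get('pcn')}  folds={cfg.get('folds')}  seed={cfg.get('seed')}\n"
        )
        return header + frame.to_string(index=False, float_format=lambda v: f"{v:.3f}")

    def save_report(self, outdir: str | Path) -> None:
        """Write the evaluation report as TSV + JSON (deterministic bytes)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.report.to_frame().to_csv(
            outdir / "report.tsv", sep="\t", index=False, float_format="%.10g"
        )
        payload = {
            "config": self.report.config,
            "per_adr": self.report.per_adr,
            "macro": self.report.macro,
        }
        (outdir / "report.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n"
        )

    def save_models(self, outdir: str | Path) -> None:
        import joblib

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        joblib.dump(
            {"adr_models": self.adr_models, "config": self.report.config},
            outdir / "models.joblib",
        )
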