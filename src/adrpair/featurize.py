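"""Binary presence/absence encoding of drugs and drug pairs.

A drug vector is the concatenation of four binary blocks (substructures,
targets, substituents, pathways); with the full catalog sizes of
881/3255/1075/1983 this gives a 7194-dimensional vector.  A pair vector
appends the second drug's vector to the first (canonical pair order), so
the full-scale pair dimension is 14,388.  Vectors are held sparse (CSR)
and densified only where a downstream step needs it (PCA).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .io import FEATURE_NAMESPACES, DrugCatalog, DrugRecord, FeatureCatalog


class UnknownFeatureError(KeyError):
    """A record's feature ID is absent from the namespace catalog."""


def encode_drug(
    record: DrugRecord, catalogs: Mapping[str, FeatureCatalog]
) -> sp.csr_matrix:
    """Encode one drug as a 1 x L sparse binary row vector.

    Bit i of block k is 1 iff the k-th catalog's i-th feature ID is in the
    record's corresponding set.  Block order is fixed:
    substructures, targets, substituents, pathways.
    """
    cols: list[int] = []
    offset = 0
    for ns in FEATURE_NAMESPACES:
        cat = catalogs[ns]
        index = cat.index
        for fid in record.feature_set(ns):
            if fid not in index:
                raise UnknownFeatureError(
                    f"feature {fid!r} of drug {record.drug_id!r} not in "
                    f"namespace {ns!r}"
                )
            cols.append(offset + index[fid])
        offset += len(cat)
    cols_arr = np.array(sorted(cols), dtype=np.int64)
    data = np.ones(len(cols_arr), dtype=np.int8)
    return sp.csr_matrix(
        (data, cols_arr, np.array([0, len(cols_arr)])), shape=(1, offset)
    )


def encode_all_drugs(catalog: DrugCatalog) -> dict[str, sp.csr_matrix]:
    """Encode every drug in the catalog; keys are drug IDs."""
    return {d: encode_drug(r, catalog.catalogs) for d, r in catalog.drugs.items()}


def encode_pair(
    a: str, b: str, vectors: Mapping[str, sp.csr_matrix]
) -> sp.csr_matrix:
    """Concatenate the two drug vectors of a canonical pair (1 x 2L).

    Slicing the result at L recovers both drug vectors exactly.
    """
    try:
        va, vb = vectors[a], vectors[b]
    except KeyError as e:
        raise KeyError(f"drug {e.args[0]!r} has no encoded vector") from None
    return sp.hstack([va, vb], format="csr")


def build_matrix(
    pairs: Sequence[tuple[str, str]], vectors: Mapping[str, sp.csr_matrix]
) -> sp.csr_matrix:
    """Stack pair vectors into a (n_pairs x 2L) sparse matrix.

    Row i equals ``encode_pair(*pairs[i])``; duplicate input pairs yield
    duplicate rows (no dedup at this layer).
    """
    if not pairs:
        some = next(iter(vectors.values()), None)
        width = 2 * some.shape[1] if some is not None else 0
        return sp.csr_matrix((0, width), dtype=np.int8)
    rows = []
    for i, (a, b) in enumerate(pairs):
        try:
            rows.append(encode_pair(a, b, vectors))
        except KeyError as e:
            raise KeyError(f"row {i}: {e.args[0]}") from None
    return sp.vstack(rows, format="csr")


def export_matrix(
    matrix: sp.spmatrix,
    pairs: Sequence[tuple[str, str]],
    mtx_path: str | Path,
    index_path: str | Path,
) -> None:
    """Write the pair matrix as MatrixMarket plus a row-index TSV of pair IDs."""
    from scipy.io import mmwrite

    mmwrite(str(mtx_path), matrix.tocoo())
    with open(index_path, "w") as fh:
        fh.write("row\tdrug_a\tdrug_b\n")
        for i, (a, b) in enumerate(pairs):
            fh.write(f"{i}\t{a}\t{b}\n")
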