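"""Candidate synthetase identification from shared identity parts.

A chimera designed around the identity parts of a reference tRNA should
be acylated by synthetases whose cognate tRNAs carry the same (or nearly
the same) identity parts.  This module scans a cleaned tRNA database for
such tRNAs:

1. the database is sliced to the isoacceptor class of interest and the
   identity parts of every tRNA are concatenated; unique concatenations
   ("concatenated identity parts") are kept with full organism/gene
   provenance,
2. candidates with more than ``max_mismatch`` mismatches *at identity
   element positions* relative to the reference tRNA(s) are discarded
   (mismatches elsewhere are reported but never filtered on),
3. a pairwise dissimilarity matrix (1 - fractional identity of a global
   alignment; 0 = identical, 1 = no homology) supports a similarity
   neighborhood query around the reference, and
4. optionally, a 2D UMAP embedding with HDBSCAN cluster labels is added
   as a visual aid; the filtered report never depends on it.

The organisms carrying surviving tRNAs are the places to look for
candidate synthetases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import Align

from . import parts as P
from .db import TrnaRecord
from .identity import IdentityTable

log = logging.getLogger(__name__)

DEFAULT_IDENTITY_PARTS = ("acceptor_stem", "disc_cca")


@dataclass
class ConcatIdentityPart:
    """A unique concatenation of identity-part regions with provenance."""

    sequence: str
    gene_ids: List[str]
    organisms: List[str]
    element_offsets: Tuple[int, ...]  # identity-element positions, 0-based


@dataclass
class RsidConfig:
    isoacceptor: str
    reference_ids: Tuple[str, ...]
    identity_parts: Tuple[str, ...] = DEFAULT_IDENTITY_PARTS
    max_mismatch: int = 1
    similarity_threshold: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        if not 0.0 <= self.similarity_threshold <= 1.0:
            raise ValueError("similarity threshold must lie in [0, 1]")


def concat_positions(identity_parts: Sequence[str]) -> List[int]:
    """Canonical positions of the concatenation, in concatenation order."""
    out: List[int] = []
    for name in identity_parts:
        out.extend(P.PART_BY_NAME[name].positions)
    return out


def build_concat_parts(
    records: Sequence[TrnaRecord],
    isoacceptor: str,
    identity_parts: Sequence[str] = DEFAULT_IDENTITY_PARTS,
    table: Optional[IdentityTable] = None,
) -> List[ConcatIdentityPart]:
    """Deduplicated concatenated identity parts for one isoacceptor class."""
    subset = [r for r in records if r.isoacceptor == isoacceptor]
    if not subset:
        raise ValueError(f"no records in isoacceptor class {isoacceptor!r}")
    positions = concat_positions(identity_parts)
    if table is not None:
        element_positions = set()
        for iso in table.isoacceptors:
            element_positions |= table.positions_for(iso)
        offsets = tuple(
            i for i, pos in enumerate(positions) if pos in element_positions
        )
    else:
        offsets = tuple(range(len(positions)))
    seen: Dict[str, ConcatIdentityPart] = {}
    for r in subset:
        seq = "".join(P.degap(r.parts[name]) for name in identity_parts)
        if seq in seen:
            seen[seq].gene_ids.append(r.gene_id)
            seen[seq].organisms.append(r.organism)
        else:
            seen[seq] = ConcatIdentityPart(seq, [r.gene_id], [r.organism], offsets)
    return sorted(seen.values(), key=lambda c: c.sequence)


def mismatch_counts(a: str, b: str, offsets: Sequence[int]) -> int:
    return sum(1 for i in offsets if a[i] != b[i])


def mismatch_filter(
    candidates: Sequence[ConcatIdentityPart],
    references: Sequence[ConcatIdentityPart],
    max_mismatch: int = 1,
) -> List[ConcatIdentityPart]:
    """Keep candidates within ``max_mismatch`` identity-element mismatches
    of the closest reference; length-incompatible candidates are skipped
    and logged."""
    kept: List[ConcatIdentityPart] = []
    for cand in candidates:
        dists = []
        for ref in references:
            if len(cand.sequence) != len(ref.sequence):
                log.warning(
                    "length mismatch for %s vs reference; skipped",
                    cand.gene_ids[0],
                )
                continue
            dists.append(
                mismatch_counts(cand.sequence, ref.sequence, ref.element_offsets)
            )
        if dists and min(dists) <= max_mismatch:
            kept.append(cand)
    return kept


_ALIGNER = Align.PairwiseAligner(
    mode="global", match_score=1, mismatch_score=0, gap_score=0
)


def fractional_identity(a: str, b: str) -> float:
    """Matches in the best global alignment over the longer length."""
    if not a or not b:
        return 0.0
    matches = _ALIGNER.score(a, b)
    return matches / max(len(a), len(b))


def dissimilarity_matrix(seqs: Sequence[str]) -> np.ndarray:
    """Pairwise 1 - fractional identity; symmetric, zero diagonal."""
    n = len(seqs)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = 1.0 - fractional_identity(seqs[i], seqs[j])
    return m


def neighbors(
    reference_index: int, matrix: np.ndarray, threshold: float = 0.2
) -> List[int]:
    """Indices within ``threshold`` dissimilarity of the reference."""
    return [
        int(i)
        for i in range(matrix.shape[0])
        if matrix[reference_index, i] <= threshold + 1e-12
    ]


def embed_and_cluster(
    matrix: np.ndarray, seed: int = 0, min_cluster_size: int = 3
) -> Tuple[np.ndarray, np.ndarray]:
    """2D embedding and density-based cluster labels for a matrix.

    UMAP on the precomputed dissimilarities followed by HDBSCAN on the
    embedding; noise points are labeled -1.  With fewer than five points
    clustering is skipped (all points unclustered) and a classical MDS
    embedding is returned instead.  Deterministic under a fixed seed.
    """
    n = matrix.shape[0]
    if n < 5:
        import warnings

        from sklearn.manifold import MDS

        labels = np.full(n, -1, dtype=int)
        if n == 1:
            return np.zeros((1, 2)), labels
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            emb = MDS(
                n_components=2,
                dissimilarity="precomputed",
                random_state=seed,
                normalized_stress="auto",
            ).fit_transform(matrix)
        return emb, labels
    import warnings

    import umap
    from sklearn.cluster import HDBSCAN

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # Keep the neighborhood smaller than plausible group sizes so
        # tight duplicate groups stay separable in the embedding.
        emb = umap.UMAP(
            n_components=2,
            metric="precomputed",
            n_neighbors=max(2, min(15, n // 2)),
            random_state=seed,
        ).fit_transform(matrix)
    labels = HDBSCAN(min_cluster_size=min(min_cluster_size, n)).fit_predict(emb)
    return np.asarray(emb), np.asarray(labels, dtype=int)


def run_rsid(
    records: Sequence[TrnaRecord],
    config: RsidConfig,
    table: Optional[IdentityTable] = None,
    precomputed_matrix: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Full scan: concatenate, filter, embed, and report.

    Returns one row per surviving concatenated identity part and
    contributing gene, with organism provenance, full-sequence mismatch
    count (reported, never filtered on), cluster label and embedding
    coordinates.
    """
    concat = build_concat_parts(
        records, config.isoacceptor, config.identity_parts, table
    )
    by_gene = {g: c for c in concat for g in c.gene_ids}
    refs = []
    for rid in config.reference_ids:
        if rid not in by_gene:
            raise ValueError(f"reference gene id not in database: {rid}")
        refs.append(by_gene[rid])
    survivors = mismatch_filter(concat, refs, config.max_mismatch)
    seqs = [c.sequence for c in survivors]
    if precomputed_matrix is not None:
        matrix = np.asarray(precomputed_matrix, dtype=float)
        if matrix.shape != (len(seqs), len(seqs)):
            raise ValueError("precomputed matrix shape does not match survivors")
    else:
        matrix = dissimilarity_matrix(seqs)
    emb, labels = embed_and_cluster(matrix, seed=config.seed)
    ref_seq = refs[0].sequence
    rows = []
    for i, c in enumerate(survivors):
        near = (
            min(
                1.0 - fractional_identity(c.sequence, r.sequence) for r in refs
            )
            <= config.similarity_threshold + 1e-12
        )
        for gene, org in zip(c.gene_ids, c.organisms):
            rows.append(
                {
                    "gene_id": gene,
                    "identity_parts": c.sequence,
                    "organism": org,
                    "element_mismatches": min(
                        mismatch_counts(c.sequence, r.sequence, r.element_offsets)
                        for r in refs
                        if len(r.sequence) == len(c.sequence)
                    ),
                    "full_mismatches": sum(
                        x != y for x, y in zip(c.sequence, ref_seq)
                    )
                    if len(c.sequence) == len(ref_seq)
                    else -1,
                    "within_similarity": near,
                    "cluster": int(labels[i]),
                    "umap_x": float(emb[i, 0]),
                    "umap_y": float(emb[i, 1]),
                }
            )
    return pd.DataFrame(rows)
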