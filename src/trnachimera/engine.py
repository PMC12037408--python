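"""Combinatorial chimera generation and the filters around it.

A design run fixes the parts of a target tRNA that carry identity elements
for its cognate synthetase and combinatorially varies the remaining parts
using sequences harvested from the same isoacceptor class:

1. :func:`filter_parts` removes variable-part sequences that break basic
   structural rules (strict Watson-Crick paired strands, short variable
   loops, a U in the 8-9 linker, an A opening the D-loop),
2. :func:`select_exemplars` ranks parts by host part-identity score,
   keeps the lowest-scoring top-N and collapses them to affinity-
   propagation exemplars on edit distance,
3. :func:`generate_chimeras` streams the Cartesian product of all part
   choices, and :func:`length_filter` / :func:`stringency_filter` prune
   it by length and by maximum host sequence-identity score, with the
   stringency threshold walked down until the survivor pool fits a
   target size.

:func:`crtm_generate` implements the scheme-based alternative: replace
named regions of a parent tRNA with the corresponding regions of donor
isoacceptor tRNAs.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from itertools import product
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

from . import parts as P
from . import select as S
from .db import TrnaRecord
from .identity import IdentityTable, PartScore, SeqScoreVector, part_identity_score

log = logging.getLogger(__name__)

VARIABLE_PARTS: Tuple[str, ...] = tuple(
    p.name for p in P.PART_TYPES if p.role == "variable"
)


@dataclass(frozen=True, slots=True)
class PartChoice:
    """One candidate sequence for one part slot."""

    part_type: str
    seq: str  # aligned, serialized
    source: str  # gene id the sequence came from
    deg_len: int

    @classmethod
    def make(cls, part_type: str, seq: str, source: str) -> "PartChoice":
        return cls(part_type, seq, source, len(P.degap(seq)))


@dataclass(slots=True)
class ChimeraDesign:
    """An assembled chimera with per-part provenance and audit trail."""

    choices: Tuple[PartChoice, ...]  # in canonical part order
    anticodon: str
    score: Optional[SeqScoreVector] = None
    folds: dict = field(default_factory=dict)  # anticodon -> FoldResult
    audit: list = field(default_factory=list)
    ensemble: Optional[object] = None  # EnsembleFoldResult after the sweep

    @property
    def length(self) -> int:
        return sum(c.deg_len for c in self.choices)

    def parts(self, anticodon: Optional[str] = None) -> Dict[str, str]:
        m = {c.part_type: c.seq for c in self.choices}
        return P.set_anticodon(m, anticodon or self.anticodon)

    def assembled(self, anticodon: Optional[str] = None) -> str:
        return P.assemble(self.parts(anticodon))

    @property
    def provenance(self) -> Dict[str, str]:
        return {c.part_type: c.source for c in self.choices}


@dataclass
class RunConfig:
    """Every knob of a chimera design run."""

    target_gene_id: str
    isoacceptor: str
    anticodons: Tuple[str, ...] = ("CTA",)
    fixed_parts: Tuple[str, ...] = ("acceptor_stem", "disc_cca")
    cluster_parts: int = 200
    min_cluster_size: int = 15
    length_filt: int = 79
    stringency_start: float = 0.5
    stringency_min: float = 0.0
    stringency_target: int = 2_500_000
    stringency_step: float = 0.05
    frequency: float = 0.30
    diversity: float = 10.0
    final_frequency: float = 0.50
    final_diversity: Optional[float] = 8.0
    num_trnas: int = 4
    automatic: bool = True
    mismatch_threshold: Optional[int] = None
    num_iterations: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stringency_step <= 0:
            raise ValueError("stringency step must be > 0")
        if not 0 <= self.frequency <= 1 or not 0 <= self.final_frequency <= 1:
            raise ValueError("frequency thresholds must lie in [0, 1]")
        if self.num_iterations < 1:
            raise ValueError("num_iterations must be >= 1")


# ---------------------------------------------------------------------------
# Part filtering


def _wc_paired(chunk5: str, chunk3: str) -> bool:
    s5, s3 = P.degap(chunk5), P.degap(chunk3)
    if len(s5) != len(s3):
        return False
    return all(P.WC.get(a) == b for a, b in zip(s5, reversed(s3)))


def part_passes(part_type: str, seq: str) -> Optional[str]:
    """None if the part passes the default rules, else the failed rule."""
    pt = P.PART_BY_NAME[part_type]
    chunks = P.split_regions(part_type, seq)
    if any(c not in "ACGT-" for chunk in chunks for c in chunk):
        return "alphabet"
    if pt.paired and not _wc_paired(chunks[0], chunks[1]):
        return "watson-crick"
    if part_type == "vloop" and len(P.degap(chunks[1])) >= 8:
        return "vloop-length"
    if part_type == "unpaired_8_9" and "T" not in chunks[0]:
        return "no-uracil-8-9"
    if part_type == "dt_loops" and not P.degap(chunks[0]).startswith("A"):
        return "dloop-start"
    return None


def filter_parts(
    parts: Mapping[str, Sequence[PartChoice]],
) -> Tuple[Dict[str, List[PartChoice]], Counter]:
    """Apply the default part rules; failures are counted, never silent."""
    kept: Dict[str, List[PartChoice]] = {}
    rejected: Counter = Counter()
    for name, choices in parts.items():
        kept[name] = []
        for c in choices:
            rule = part_passes(name, c.seq)
            if rule is None:
                kept[name].append(c)
            else:
                rejected[(name, rule)] += 1
    return kept, rejected


# ---------------------------------------------------------------------------
# Exemplar selection


def select_exemplars(
    scored: Sequence[Tuple[PartChoice, float]],
    top_n: int = 200,
    min_cluster_size: int = 15,
    seed: int = 0,
) -> List[PartChoice]:
    """Lowest-scoring top-N parts collapsed to clustering exemplars.

    Pools with fewer than ``min_cluster_size`` unique sequences are
    returned unclustered.  Ties at the top-N boundary are broken by
    lexicographic sequence order.  Non-convergent clustering falls back
    to the ``min_cluster_size`` lowest-scoring sequences.
    """
    uniq: Dict[str, Tuple[PartChoice, float]] = {}
    for choice, score in scored:
        if choice.seq not in uniq or score < uniq[choice.seq][1]:
            uniq[choice.seq] = (choice, score)
    ranked = sorted(uniq.values(), key=lambda t: (t[1], t[0].seq))
    pool = [c for c, _ in ranked[:top_n]]
    if len(pool) < min_cluster_size:
        return pool
    seqs = [c.seq for c in pool]
    d = S.distance_matrix(seqs)
    ex = S.affinity_propagation_exemplars(d, seed)
    if ex is None:
        log.warning(
            "affinity propagation did not converge for part %s; keeping the "
            "%d lowest-scoring sequences",
            pool[0].part_type,
            min_cluster_size,
        )
        return pool[:min_cluster_size]
    return [pool[i] for i in ex]


# ---------------------------------------------------------------------------
# Generation and filtering


def count_chimeras(library: Mapping[str, Sequence[PartChoice]]) -> int:
    n = 1
    for name in P.PART_NAMES:
        n *= len(library[name])
    return n


def generate_chimeras(
    library: Mapping[str, Sequence[PartChoice]], anticodon: str
) -> Iterator[ChimeraDesign]:
    """Stream every combination of part choices exactly once."""
    for name in P.PART_NAMES:
        if not library.get(name):
            raise ValueError(f"empty part slot: {name}")
    slots = [tuple(library[name]) for name in P.PART_NAMES]
    for combo in product(*slots):
        yield ChimeraDesign(choices=combo, anticodon=anticodon)


def length_filter(
    designs: Iterable[ChimeraDesign],
    max_len: int = 79,
    stats: Optional[Counter] = None,
) -> Iterator[ChimeraDesign]:
    """Keep chimeras strictly shorter than ``max_len`` nucleotides."""
    for d in designs:
        if d.length < max_len:
            if stats is not None:
                stats["kept"] += 1
            yield d
        elif stats is not None:
            stats["dropped"] += 1


def stringency_filter(
    designs: Sequence[ChimeraDesign],
    start: float = 0.5,
    minimum: float = 0.0,
    target: int = 2_500_000,
    step: float = 0.05,
) -> Tuple[List[ChimeraDesign], float]:
    """Walk the max-identity-score threshold down toward a pool target.

    Keeps designs with ``max_score <= t``, lowering ``t`` from ``start``
    by ``step`` while more than ``target`` survive, stopping at the
    ``minimum`` floor even if the pool is still larger than the target.
    """
    scores = [d.score.max_score for d in designs]
    t = start

    def survivors(th: float) -> List[ChimeraDesign]:
        return [d for d, s in zip(designs, scores) if s <= th + 1e-12]

    kept = survivors(t)
    while len(kept) > target and t > minimum + 1e-12:
        t = round(t - step, 10)
        if t < minimum:
            t = minimum
        kept = survivors(t)
    for d in kept:
        d.audit.append(f"stringency<= {t:g}")
    return kept, t


def run_iterations(
    scored_parts: Mapping[str, Sequence[Tuple[PartChoice, float]]],
    fixed: Mapping[str, PartChoice],
    config: RunConfig,
) -> Tuple[List[ChimeraDesign], List[Dict[str, List[PartChoice]]]]:
    """Pooled chimera generation over one or more exemplar iterations.

    Each iteration excludes every exemplar chosen by earlier iterations
    before re-clustering, and stops early (with a warning) if any part
    pool is exhausted.  The pooled result is deduplicated on the
    assembled sequence.
    """
    used: Dict[str, set] = {n: set() for n in scored_parts}
    pooled: Dict[str, ChimeraDesign] = {}
    libraries: List[Dict[str, List[PartChoice]]] = []
    for it in range(config.num_iterations):
        library: Dict[str, List[PartChoice]] = {n: [c] for n, c in fixed.items()}
        exhausted = False
        for name, scored in scored_parts.items():
            remaining = [(c, s) for c, s in scored if c.seq not in used[name]]
            if not remaining:
                exhausted = True
                break
            library[name] = select_exemplars(
                remaining,
                top_n=config.cluster_parts,
                min_cluster_size=config.min_cluster_size,
                seed=config.seed + it,
            )
        if exhausted:
            log.warning("part pool exhausted at iteration %d; stopping early", it + 1)
            break
        libraries.append(library)
        for name in scored_parts:
            used[name].update(c.seq for c in library[name])
        for design in generate_chimeras(library, config.anticodons[0]):
            pooled.setdefault(design.assembled(), design)
    return list(pooled.values()), libraries


# ---------------------------------------------------------------------------
# Scheme-based (CRtM) generation


def load_schemes(path=None) -> List[Dict]:
    """Load replacement schemes (default: the packaged reconstruction)."""
    if path is None:
        ref = resources.files("trnachimera.data").joinpath("crtm_schemes.json")
        with ref.open("r") as fh:
            payload = json.load(fh)
    else:
        with open(path) as fh:
            payload = json.load(fh)
    return payload["schemes"]


def crtm_generate(
    parent: TrnaRecord,
    donors: Sequence[TrnaRecord],
    schemes: Sequence[Mapping],
) -> List[TrnaRecord]:
    """Replace scheme-named parts of the parent with donor parts.

    One chimera per (scheme, donor) pair; pairs whose donor lacks a
    required part are skipped and logged.
    """
    out: List[TrnaRecord] = []
    for scheme in schemes:
        names = list(scheme["parts"])
        for donor in donors:
            if donor.isoacceptor != parent.isoacceptor:
                log.warning(
                    "donor %s isoacceptor %s != parent %s; skipped",
                    donor.gene_id,
                    donor.isoacceptor,
                    parent.isoacceptor,
                )
                continue
            missing = [n for n in names if not donor.parts.get(n)]
            if missing:
                log.warning(
                    "donor %s missing part(s) %s for scheme %s; skipped",
                    donor.gene_id,
                    ",".join(missing),
                    scheme.get("name", "?"),
                )
                continue
            new_parts = dict(parent.parts)
            for n in names:
                new_parts[n] = donor.parts[n]
            out.append(
                TrnaRecord(
                    gene_id=f"{parent.gene_id}:{scheme.get('name', 'scheme')}:{donor.gene_id}",
                    organism=parent.organism,
                    isoacceptor=parent.isoacceptor,
                    anticodon=parent.anticodon,
                    parts=new_parts,
                    source="crtm",
                )
            )
    return out
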