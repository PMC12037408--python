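"""Host identity-element tables and identity scoring.

An aminoacyl-tRNA synthetase recognizes its cognate tRNAs through identity
elements: specific bases at specific canonical positions.  A chimeric tRNA
meant to be orthogonal in the host must avoid host identity elements, so
two scores quantify how host-like a sequence is:

* the **part identity score** of a single part sequence: over the part's
  positions that are identity elements for at least one host isoacceptor
  (the set *j*, |j| = k), average the fraction of the per-position host
  base multiset M_i matched by the query base.  Each isoacceptor
  contributes its unique base identities at a position once.  The score
  lies in [0, 1]; 0 means no scored position matches any host element.

* the **sequence identity score** of a full chimera, one value per host
  isoacceptor: per host tRNA gene, +1 for a match and -1 for a mismatch at
  each of that isoacceptor's element positions, divided by the number of
  scored elements, then averaged over the isoacceptor's genes.  The
  maximum entry over isoacceptors is used for filtering.  Elements inside
  a run's fixed identity parts (and, by default, the anticodon positions
  shared by all designs) are excluded from scoring.

The packaged default table is an explicitly partial reconstruction of the
E. coli identity-element set; a complete table is a user input with the
same schema (isoacceptor, gene_id, position, base).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from . import parts as P

log = logging.getLogger(__name__)


@dataclass
class IdentityTable:
    """Identity-element positions and host bases per isoacceptor gene."""

    # iso -> gene -> {position: base}
    genes: Dict[str, Dict[str, Dict[int, str]]]

    def __post_init__(self) -> None:
        for iso, genes in self.genes.items():
            for gene, bases in genes.items():
                for pos, base in bases.items():
                    if not 1 <= pos <= P.SEQ_LEN:
                        raise ValueError(
                            f"position out of range for {iso}/{gene}: {pos}"
                        )
                    if base not in P.DNA:
                        raise ValueError(
                            f"non-nucleotide base for {iso}/{gene}@{pos}: {base!r}"
                        )

    @property
    def isoacceptors(self) -> Tuple[str, ...]:
        return tuple(sorted(self.genes))

    def positions_for(self, iso: str) -> FrozenSet[int]:
        out = set()
        for bases in self.genes[iso].values():
            out.update(bases)
        return frozenset(out)

    @property
    def all_positions(self) -> FrozenSet[int]:
        out = set()
        for iso in self.genes:
            out |= self.positions_for(iso)
        return frozenset(out)

    def multiset(self, position: int) -> List[str]:
        """Host bases at a position: per isoacceptor, unique bases once."""
        out: List[str] = []
        for iso in self.isoacceptors:
            if position not in self.positions_for(iso):
                continue
            uniq = sorted(
                {
                    bases[position]
                    for bases in self.genes[iso].values()
                    if position in bases
                }
            )
            out.extend(uniq)
        return out


@dataclass
class PartScore:
    part_type: str
    sequence: str
    score: float
    contributions: Dict[int, float]
    defined: bool = True

    @property
    def k(self) -> int:
        return len(self.contributions)


@dataclass
class SeqScoreVector:
    scores: Dict[str, float]
    omitted: Tuple[str, ...] = ()

    @property
    def max_score(self) -> float:
        return max(self.scores.values())


def _part_char(part_name: str, aligned: str, position: int) -> str:
    pt = P.PART_BY_NAME[part_name]
    chunks = P.split_regions(part_name, aligned)
    for (lo, hi), chunk in zip(pt.regions, chunks):
        if lo <= position <= hi:
            off = position - lo
            return chunk[off] if off < len(chunk) else P.GAP
    raise ValueError(f"position {position} not in part {part_name}")


def part_identity_score(
    part_name: str, aligned: str, table: IdentityTable
) -> PartScore:
    """Score one part sequence against the host identity table.

    When the part contains no identity position (k = 0) the score is
    reported as 0 for ranking purposes and flagged as undefined.
    """
    positions = sorted(set(P.PART_BY_NAME[part_name].positions) & table.all_positions)
    if not positions:
        log.info("no identity positions in part %s; score undefined", part_name)
        return PartScore(part_name, aligned, 0.0, {}, defined=False)
    contributions: Dict[int, float] = {}
    for i in positions:
        m = table.multiset(i)
        n_i = _part_char(part_name, aligned, i)
        contributions[i] = m.count(n_i) / len(m)
    score = sum(contributions.values()) / len(positions)
    return PartScore(part_name, aligned, score, contributions)


def sequence_identity_score(
    parts: Mapping[str, str],
    table: IdentityTable,
    excluded_positions: Iterable[int] = (),
    exclude_anticodon: bool = True,
) -> SeqScoreVector:
    """Per-isoacceptor +/-1 identity score of an assembled chimera."""
    excluded = set(excluded_positions)
    if exclude_anticodon:
        excluded.update(P.ANTICODON_POSITIONS)
    scores: Dict[str, float] = {}
    omitted: List[str] = []
    for iso in table.isoacceptors:
        gene_scores: List[float] = []
        for gene, bases in sorted(table.genes[iso].items()):
            pos = [p for p in sorted(bases) if p not in excluded]
            if not pos:
                continue
            total = sum(
                1 if P.char_at(parts, p) == bases[p] else -1 for p in pos
            )
            gene_scores.append(total / len(pos))
        if not gene_scores:
            omitted.append(iso)
            log.info("all identity positions excluded for %s; entry omitted", iso)
            continue
        scores[iso] = sum(gene_scores) / len(gene_scores)
    return SeqScoreVector(scores, tuple(omitted))


def fixed_part_positions(fixed_parts: Iterable[str]) -> FrozenSet[int]:
    """Canonical positions covered by the given (identity) parts."""
    out = set()
    for name in fixed_parts:
        out.update(P.PART_BY_NAME[name].positions)
    return frozenset(out)


def load_identity_table(path_or_buffer) -> IdentityTable:
    """Load a TSV of (isoacceptor, gene_id, position, base)."""
    df = pd.read_csv(path_or_buffer, sep="\t", dtype=str)
    for col in ("isoacceptor", "gene_id", "position", "base"):
        if col not in df.columns:
            raise ValueError(f"identity table missing column: {col}")
    genes: Dict[str, Dict[str, Dict[int, str]]] = {}
    for _, row in df.iterrows():
        pos = int(row["position"])
        base = row["base"].strip().upper().replace("U", "T")
        genes.setdefault(row["isoacceptor"], {}).setdefault(row["gene_id"], {})[
            pos
        ] = base
    return IdentityTable(genes)


def default_identity_table() -> IdentityTable:
    """The packaged (partial) host identity-element table."""
    ref = resources.files("trnachimera.data").joinpath("identity_elements.tsv")
    with ref.open("r") as fh:
        return load_identity_table(fh)


def write_identity_table(table: IdentityTable, path) -> None:
    """Write a table back to the TSV schema accepted by the loader."""
    rows = [
        {"isoacceptor": iso, "gene_id": gene, "position": pos, "base": base}
        for iso, genes in sorted(table.genes.items())
        for gene, bases in sorted(genes.items())
        for pos, base in sorted(bases.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_part_scores(scores: Sequence[PartScore], path) -> None:
    rows = [
        {
            "part_type": s.part_type,
            "sequence": s.sequence,
            "score": s.score,
            "k": s.k,
            "defined": s.defined,
        }
        for s in scores
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
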