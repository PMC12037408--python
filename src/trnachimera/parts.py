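"""Canonical nine-part model of the tRNA cloverleaf.

A tRNA gene is addressed by the canonical 1-based numbering 1..76 and split
into nine structurally self-contained parts, chosen so that secondary and
tertiary base-pairing interactions stay *within* a part:

========================  =======================
part                      canonical positions
========================  =======================
acceptor_stem             1-7 + 66-72
unpaired_8_9              8-9
d_arm                     10-13 + 22-25
dt_loops                  14-21 + 54-60
vloop                     26 + 44-48
ac_stem                   27-31 + 39-43
ac_loop                   32-38  (anticodon 34-36)
t_arm                     49-53 + 61-65
disc_cca                  73-76  (discriminator + CCA)
========================  =======================

Parts with two regions (both strands of a helix, or the merged D/T loops)
are serialized with an underscore between the regions, e.g. the D/T-loop
part ``AACTGGCA_TTCGAGC``.  Sequences are stored in the DNA alphabet
(A, C, G, T) with ``-`` as the alignment gap; conversion to RNA happens
only at the folding boundary.

The D-loop occupies eight aligned slots (positions 14-21).  The variable
loop occupies canonical slots 44-48 but its region may carry up to seven
nucleotides for database entries with longer loops; canonical positions
44-48 address the first five characters of that region.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

GAP = "-"
SEP = "_"
DNA = "ACGT"

# Watson-Crick complement (DNA alphabet, strict: no wobble).
WC = {"A": "T", "T": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class PartType:
    """One of the nine canonical parts.

    ``regions`` are inclusive 1-based canonical coordinate ranges in 5'->3'
    order.  ``paired`` marks parts whose two regions are the strands of one
    helix and must base-pair.  ``role`` is ``"identity"`` for parts that can
    carry the fixed identity elements of a design run, else ``"variable"``.
    """

    name: str
    regions: Tuple[Tuple[int, int], ...]
    paired: bool = False
    role: str = "variable"

    @property
    def positions(self) -> Tuple[int, ...]:
        out: List[int] = []
        for lo, hi in self.regions:
            out.extend(range(lo, hi + 1))
        return tuple(out)

    def region_widths(self) -> Tuple[int, ...]:
        return tuple(hi - lo + 1 for lo, hi in self.regions)


PART_TYPES: Tuple[PartType, ...] = (
    PartType("acceptor_stem", ((1, 7), (66, 72)), paired=True, role="identity"),
    PartType("unpaired_8_9", ((8, 9),)),
    PartType("d_arm", ((10, 13), (22, 25)), paired=True),
    PartType("dt_loops", ((14, 21), (54, 60))),
    PartType("vloop", ((26, 26), (44, 48))),
    PartType("ac_stem", ((27, 31), (39, 43)), paired=True),
    PartType("ac_loop", ((32, 38),), role="identity"),
    PartType("t_arm", ((49, 53), (61, 65)), paired=True),
    PartType("disc_cca", ((73, 76),), role="identity"),
)

PART_BY_NAME: Dict[str, PartType] = {p.name: p for p in PART_TYPES}
PART_NAMES: Tuple[str, ...] = tuple(p.name for p in PART_TYPES)

SEQ_LEN = 76
ANTICODON_POSITIONS = (34, 35, 36)

# Canonical 5'->3' traversal as (part name, region index) pairs.
CANONICAL_ORDER: Tuple[Tuple[str, int], ...] = (
    ("acceptor_stem", 0),
    ("unpaired_8_9", 0),
    ("d_arm", 0),
    ("dt_loops", 0),
    ("d_arm", 1),
    ("vloop", 0),
    ("ac_stem", 0),
    ("ac_loop", 0),
    ("ac_stem", 1),
    ("vloop", 1),
    ("t_arm", 0),
    ("dt_loops", 1),
    ("t_arm", 1),
    ("acceptor_stem", 1),
    ("disc_cca", 0),
)


def _check_disjoint_cover() -> None:
    seen: Dict[int, str] = {}
    for p in PART_TYPES:
        for pos in p.positions:
            if pos in seen:
                raise AssertionError(f"position {pos} in both {seen[pos]} and {p.name}")
            seen[pos] = p.name
    if set(seen) != set(range(1, SEQ_LEN + 1)):
        raise AssertionError("part position sets do not cover 1..76")


_check_disjoint_cover()


def degap(seq: str) -> str:
    """Remove alignment gaps (and region separators)."""
    return seq.replace(GAP, "").replace(SEP, "")


def split_regions(part_name: str, aligned: str) -> List[str]:
    """Split a serialized part into its per-region chunks."""
    part = PART_BY_NAME[part_name]
    chunks = aligned.split(SEP)
    if len(chunks) != len(part.regions):
        raise ValueError(
            f"part {part_name} expects {len(part.regions)} region(s), "
            f"got {len(chunks)} in {aligned!r}"
        )
    return chunks


def join_regions(chunks: Sequence[str]) -> str:
    return SEP.join(chunks)


def segment(full: str) -> Dict[str, str]:
    """Cut a 76-slot aligned sequence into the nine serialized parts."""
    if len(full) != SEQ_LEN:
        raise ValueError(
            f"expected a {SEQ_LEN}-position aligned sequence, got length {len(full)}"
        )
    out: Dict[str, List[str]] = {p.name: [] for p in PART_TYPES}
    for name, ridx in CANONICAL_ORDER:
        lo, hi = PART_BY_NAME[name].regions[ridx]
        out[name].append(full[lo - 1 : hi])
    return {name: join_regions(chunks) for name, chunks in out.items()}


def assemble(parts: Mapping[str, str]) -> str:
    """Assemble nine parts into the full degapped 5'->3' sequence."""
    missing = [n for n in PART_NAMES if n not in parts]
    if missing:
        raise ValueError(f"missing part(s): {', '.join(missing)}")
    chunks = {name: split_regions(name, parts[name]) for name in PART_NAMES}
    return "".join(degap(chunks[name][ridx]) for name, ridx in CANONICAL_ORDER)


def assembled_length(parts: Mapping[str, str]) -> int:
    """Degapped length of the assembled sequence (no string build)."""
    return sum(len(degap(parts[name])) for name in PART_NAMES)


def aligned_full(parts: Mapping[str, str]) -> str:
    """Concatenate aligned regions in canonical order (gaps retained)."""
    chunks = {name: split_regions(name, parts[name]) for name in PART_NAMES}
    return "".join(chunks[name][ridx] for name, ridx in CANONICAL_ORDER)


def char_at(parts: Mapping[str, str], position: int) -> str:
    """Nucleotide (or gap) at a canonical position of a part map."""
    for p in PART_TYPES:
        for ridx, (lo, hi) in enumerate(p.regions):
            if lo <= position <= hi:
                chunk = split_regions(p.name, parts[p.name])[ridx]
                off = position - lo
                return chunk[off] if off < len(chunk) else GAP
    raise ValueError(f"canonical position out of range: {position}")


def part_of_position(position: int) -> str:
    for p in PART_TYPES:
        if position in p.positions:
            return p.name
    raise ValueError(f"canonical position out of range: {position}")


def set_anticodon(target, anticodon: str):
    """Return a copy with canonical positions 34-36 set to ``anticodon``.

    ``target`` may be a part map (dict) or a 76-slot aligned string; the
    result has the same type.  Only positions 34-36 change.
    """
    anticodon = anticodon.upper()
    if len(anticodon) != 3 or any(c not in DNA for c in anticodon):
        raise ValueError(f"anticodon must be a 3-mer over {DNA}: {anticodon!r}")
    if isinstance(target, str):
        if len(target) != SEQ_LEN:
            raise ValueError("expected a 76-position aligned sequence")
        return target[:33] + anticodon + target[36:]
    parts = dict(target)
    loop = split_regions("ac_loop", parts["ac_loop"])[0]
    # ac_loop covers 32-38; the anticodon sits at offsets 2-4.
    parts["ac_loop"] = loop[:2] + anticodon + loop[5:]
    return parts


def get_anticodon(parts: Mapping[str, str]) -> str:
    loop = split_regions("ac_loop", parts["ac_loop"])[0]
    return loop[2:5]


def part_table() -> List[dict]:
    """Part definitions as plain dicts (for JSON/TSV export)."""
    return [
        {
            "name": p.name,
            "regions": [list(r) for r in p.regions],
            "paired": p.paired,
            "role": p.role,
        }
        for p in PART_TYPES
    ]


def export_part_table(path) -> None:
    with open(path, "w") as fh:
        json.dump(part_table(), fh, indent=2)


def random_aligned_sequence(rng: random.Random) -> str:
    """A random 76-slot aligned sequence (uniform bases, no gaps)."""
    return "".join(rng.choice(DNA) for _ in range(SEQ_LEN))
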