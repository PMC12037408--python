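"""Reading, validating and cleaning aligned tRNA gene tables.

The on-disk format is a tab-separated table with one tRNA gene per row and
columns ``gene_id``, ``organism``, ``isoacceptor``, ``anticodon`` followed
by the nine part columns (see :mod:`trnachimera.parts`).  A column-mapping
dict supports other dialects.

Cleaning normalizes each record to the conventions the design pipeline
expects: U->T, D-loop aligned to eight slots with the conserved GG motif at
aligned positions 5-6 (canonical 18-19), positions 74-76 forced to CCA and
the anticodon set to a configurable default (CTA, the amber suppressor).
Records that cannot be normalized are rejected with a reason code, never
silently dropped: the cleaned set and the reject log always partition the
input.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from . import parts as P

REQUIRED_COLUMNS = ("gene_id", "organism", "isoacceptor", "anticodon") + P.PART_NAMES

ISOACCEPTORS = (
    "Ala Arg Asn Asp Cys Gln Glu Gly His Ile "
    "Leu Lys Met Phe Pro Ser Thr Trp Tyr Val"
).split()

DEFAULT_ANTICODON = "CTA"

# GG motif of the D-loop sits at aligned slots 5-6 (0-based 4-5),
# i.e. canonical positions 18-19.
DLOOP_WIDTH = 8
GG_SLOT = 4


class RejectReason(str, Enum):
    MISSING_FIELD = "missing-field"
    AMBIGUOUS_BASE = "ambiguous-base"
    DLOOP_UNALIGNABLE = "dloop-unalignable"
    PART_SIZE = "part-size"
    DUPLICATE_ID = "duplicate-id"


@dataclass
class Reject:
    gene_id: str
    reason: RejectReason
    detail: str = ""


@dataclass
class TrnaRecord:
    """One aligned tRNA gene with its nine canonical parts."""

    gene_id: str
    organism: str
    isoacceptor: str
    anticodon: str
    parts: Dict[str, str]
    source: str = "raw"

    def assembled(self) -> str:
        return P.assemble(self.parts)

    def copy(self) -> "TrnaRecord":
        return replace(self, parts=dict(self.parts))


def parse_db(
    path_or_buffer,
    column_map: Optional[Mapping[str, str]] = None,
) -> Tuple[List[TrnaRecord], List[Reject]]:
    """Parse a TSV table into raw records.

    Rows with an empty/missing required field are reported as rejects
    (``missing-field``); a missing required *column* is fatal.
    """
    try:
        df = pd.read_csv(path_or_buffer, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return [], []
    if column_map:
        df = df.rename(columns=dict(column_map))
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column: {col}")
    records: List[TrnaRecord] = []
    rejects: List[Reject] = []
    for idx, row in df.iterrows():
        gene_id = row["gene_id"] if isinstance(row["gene_id"], str) else f"row{idx}"
        empty = [
            c
            for c in REQUIRED_COLUMNS
            if not isinstance(row[c], str) or not row[c].strip()
        ]
        if empty:
            rejects.append(
                Reject(gene_id, RejectReason.MISSING_FIELD, ",".join(empty))
            )
            continue
        records.append(
            TrnaRecord(
                gene_id=row["gene_id"].strip(),
                organism=row["organism"].strip(),
                isoacceptor=row["isoacceptor"].strip(),
                anticodon=row["anticodon"].strip().upper(),
                parts={n: row[n].strip().upper() for n in P.PART_NAMES},
            )
        )
    return records, rejects


def align_dloop(
    dloop: str, dictionary: Optional[Mapping[str, str]] = None
) -> Optional[str]:
    """Align a degapped D-loop to the eight-slot consensus.

    A curated dictionary is consulted first.  Otherwise six-nucleotide
    loops get ``--`` between the 2nd and 3rd nucleotides and seven-
    nucleotide loops get ``-`` between the 3rd and 4th; the result must
    place the GG motif at aligned slots 5-6 or alternative single-block
    gap placements are tried 5'-first.  Returns ``None`` when no valid
    placement exists.
    """
    dloop = P.degap(dloop).upper()
    if dictionary and dloop in dictionary:
        hit = dictionary[dloop]
        return hit if _gg_ok(hit) else None
    n = len(dloop)
    if n < 6:
        return None
    if n == 8:
        return dloop if _gg_ok(dloop) else None
    if n > 8:
        # Longer loops are kept as supplied only when GG already sits at
        # the canonical slots.
        return dloop if _gg_ok(dloop) else None
    gap = "-" * (8 - n)
    canonical_cut = 2 if n == 6 else 3
    for cut in [canonical_cut] + [i for i in range(n + 1) if i != canonical_cut]:
        cand = dloop[:cut] + gap + dloop[cut:]
        if _gg_ok(cand):
            return cand
    return None


def _gg_ok(aligned: str) -> bool:
    return len(aligned) >= GG_SLOT + 2 and aligned[GG_SLOT : GG_SLOT + 2] == "GG"


def _alphabet_ok(seq: str) -> bool:
    return all(c in "ACGT-_" for c in seq)


def _clean_one(
    rec: TrnaRecord,
    anticodon: str,
    dloop_dict: Optional[Mapping[str, str]],
) -> Tuple[Optional[TrnaRecord], Optional[Reject]]:
    parts = {}
    for name in P.PART_NAMES:
        seq = rec.parts.get(name)
        if seq is None or not seq.strip():
            return None, Reject(rec.gene_id, RejectReason.MISSING_FIELD, name)
        parts[name] = seq.strip().upper().replace("U", "T")
    if not rec.isoacceptor or not rec.organism:
        return None, Reject(rec.gene_id, RejectReason.MISSING_FIELD, "metadata")
    for name, seq in parts.items():
        if not _alphabet_ok(seq):
            bad = sorted({c for c in seq if c not in "ACGT-_"})
            return None, Reject(
                rec.gene_id, RejectReason.AMBIGUOUS_BASE, f"{name}:{''.join(bad)}"
            )
    # Region shape checks.
    for name in P.PART_NAMES:
        try:
            chunks = P.split_regions(name, parts[name])
        except ValueError as exc:
            return None, Reject(rec.gene_id, RejectReason.PART_SIZE, str(exc))
        pt = P.PART_BY_NAME[name]
        for ridx, ((lo, hi), chunk) in enumerate(zip(pt.regions, chunks)):
            width = hi - lo + 1
            deg = len(P.degap(chunk))
            if name == "dt_loops" and ridx == 0:
                continue  # D-loop handled below
            if name == "vloop" and ridx == 1:
                if deg > 7:
                    return None, Reject(
                        rec.gene_id, RejectReason.PART_SIZE, f"vloop {deg} nt"
                    )
                continue
            if len(chunk) != width or deg != width:
                return None, Reject(
                    rec.gene_id,
                    RejectReason.PART_SIZE,
                    f"{name} region {lo}-{hi}: got {chunk!r}",
                )
    # D-loop alignment.
    dchunks = P.split_regions("dt_loops", parts["dt_loops"])
    aligned = align_dloop(dchunks[0], dloop_dict)
    if aligned is None:
        return None, Reject(
            rec.gene_id, RejectReason.DLOOP_UNALIGNABLE, P.degap(dchunks[0])
        )
    parts["dt_loops"] = P.join_regions([aligned, dchunks[1]])
    # Force 74-76 to CCA (discriminator kept).
    disc = parts["disc_cca"]
    parts["disc_cca"] = disc[0] + "CCA"
    # Default anticodon.
    parts = P.set_anticodon(parts, anticodon)
    return (
        TrnaRecord(
            gene_id=rec.gene_id,
            organism=rec.organism,
            isoacceptor=rec.isoacceptor,
            anticodon=anticodon,
            parts=parts,
            source="cleaned",
        ),
        None,
    )


def cleanup(
    records: Iterable[TrnaRecord],
    anticodon: str = DEFAULT_ANTICODON,
    dloop_dict: Optional[Mapping[str, str]] = None,
) -> Tuple[List[TrnaRecord], List[Reject]]:
    """Normalize raw records; every input lands in cleaned or rejected."""
    cleaned: List[TrnaRecord] = []
    rejects: List[Reject] = []
    for rec in records:
        ok, rej = _clean_one(rec, anticodon, dloop_dict)
        if ok is not None:
            cleaned.append(ok)
        else:
            rejects.append(rej)
    return cleaned, rejects


def add_trna(
    record: TrnaRecord,
    db: List[TrnaRecord],
    anticodon: str = DEFAULT_ANTICODON,
    dloop_dict: Optional[Mapping[str, str]] = None,
) -> TrnaRecord:
    """Clean one record and append it to ``db`` (in place).

    Raises ``ValueError`` on a duplicate gene id or failed cleaning.
    """
    if any(r.gene_id == record.gene_id for r in db):
        raise ValueError(f"duplicate gene_id: {record.gene_id}")
    ok, rej = _clean_one(record, anticodon, dloop_dict)
    if ok is None:
        raise ValueError(f"record failed cleaning ({rej.reason.value}): {rej.detail}")
    db.append(ok)
    return ok


def write_db(records: Sequence[TrnaRecord], path) -> None:
    rows = [
        {
            "gene_id": r.gene_id,
            "organism": r.organism,
            "isoacceptor": r.isoacceptor,
            "anticodon": r.anticodon,
            **{n: r.parts[n] for n in P.PART_NAMES},
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def write_rejects(rejects: Sequence[Reject], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["gene_id", "reason", "detail"])
        for r in rejects:
            w.writerow([r.gene_id, r.reason.value, r.detail])


def write_fasta(records: Sequence[TrnaRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.gene_id} {r.organism} {r.isoacceptor}\n{r.assembled()}\n")


def load_dloop_dict(path) -> Dict[str, str]:
    """Load a curated D-loop alignment dictionary (TSV: raw<TAB>aligned)."""
    out: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            raw, aligned = line.split("\t")[:2]
            out[raw.upper()] = aligned.upper()
    return out
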