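"""Synthetic aligned-tRNA databases with planted ground truth.

Real tRNA gene databases are far too large to ship; this module builds
miniature ones with the same table schema and with every property the
pipeline filters on planted deliberately, so each stage can be asserted
against a manifest rather than against opaque snapshots:

* records derive from a cloverleaf-stable consensus backbone (strong
  Watson-Crick stems, short loops, conserved GG in the D-loop, a U in
  the 8-9 linker, an A opening the D-loop);
* stem mutations are always compensatory, so every uncorrupted record
  passes the Watson-Crick part filter by construction;
* identity-part groups are planted: group 0 matches the synthetic host
  identity table at every element position (sequence identity score
  +1.0), foreign groups mismatch at nearly all of them (score <= 0);
* corruption injects the malformed entries real databases contain:
  missing fields, ambiguity codes and D-loops without an alignable GG
  motif; benign 6-7 nt D-loops are also emitted and must re-align.

The manifest records every planted truth per gene id.

What this generator does *not* emulate: phylogenetic covariance between
organisms, post-transcriptional modification signals, and type-II long
variable arms.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from . import parts as P
from .db import REQUIRED_COLUMNS
from .identity import IdentityTable

# Host consensus backbone, per part (serialized, DNA alphabet).  Chosen by
# constrained search so its primary sequence folds into a high-frequency,
# low-diversity cloverleaf MFE structure under default folding parameters.
HOST_BACKBONE: Dict[str, str] = {
    "acceptor_stem": "GAGTGGC_GCCACTC",
    "unpaired_8_9": "TA",
    "d_arm": "GAGC_GCTC",
    "dt_loops": "AAACGGAA_TTCGACT",
    "vloop": "C_TTTCT",
    "ac_stem": "GCCGC_GCGGC",
    "ac_loop": "CTCTAAA",
    "t_arm": "GCATA_TATGC",
    "disc_cca": "ACCA",
}

# Identity-element positions of the synthetic host table: the acceptor
# 1-3 / 70-72 signature with the discriminator, plus D/T-loop elements.
ACCEPTOR_ELEMENTS = (1, 2, 3, 70, 71, 72, 73)
LOOP_ELEMENTS = (14, 15, 16, 20, 59, 60)

# Per-group planted signatures: (acceptor 1-3 prefix, discriminator,
# D/T-loop bases at 15/16/20/59/60).  Group 0 is the host itself; every
# foreign signature base differs from the host base at its position (the
# paired 70-72 bases differ automatically by Watson-Crick complementarity).
_FOREIGN_PREFIXES = ("CCA", "TGT", "ACT", "CTC", "TCA", "AGA", "CGT")
_FOREIGN_DISCS = ("G", "T", "C", "G", "T", "C", "G")
_FOREIGN_LOOPS = ("GGGGA", "TCTAC", "CTCGA", "GCGTC", "TGTAG", "CCCGG", "GTGTA")

# Loop positions that are never point-mutated, so planted signatures and
# cleanup-critical motifs survive mutation: D-loop start A (14), GG motif
# (18-19), the planted loop elements, the 8-9 uracil and the anticodon.
_PROTECTED = set(LOOP_ELEMENTS) | {8, 14, 18, 19, 34, 35, 36}


@dataclass
class SynthConfig:
    n_organisms: int = 50
    isoacceptors: Tuple[str, ...] = ("Trp",)
    mutation_rate: float = 0.10
    corruption_rate: float = 0.0
    n_identity_groups: int = 3
    short_dloop_rate: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.mutation_rate, self.corruption_rate, self.short_dloop_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.n_identity_groups < 1:
            raise ValueError("need at least one identity group")
        if self.n_identity_groups > 1 + len(_FOREIGN_PREFIXES):
            raise ValueError(
                f"at most {1 + len(_FOREIGN_PREFIXES)} identity groups supported"
            )
        if self.seed is None:
            raise ValueError("a seed is mandatory")


def _revcomp(s: str) -> str:
    return "".join(P.WC[c] for c in reversed(s))


def group_backbone(group: int) -> Dict[str, str]:
    """The planted part backbone for one identity group."""
    parts = dict(HOST_BACKBONE)
    if group > 0:
        host5 = HOST_BACKBONE["acceptor_stem"].split(P.SEP)[0]
        strand5 = _FOREIGN_PREFIXES[group - 1] + host5[3:]
        parts["acceptor_stem"] = strand5 + P.SEP + _revcomp(strand5)
        parts["disc_cca"] = _FOREIGN_DISCS[group - 1] + "CCA"
        l15, l16, l20, l59, l60 = _FOREIGN_LOOPS[group - 1]
        dloop, tloop = HOST_BACKBONE["dt_loops"].split(P.SEP)
        d = list(dloop)  # positions 14-21
        d[1], d[2], d[6] = l15, l16, l20
        t = list(tloop)  # positions 54-60
        t[5], t[6] = l59, l60
        parts["dt_loops"] = "".join(d) + P.SEP + "".join(t)
    return parts


def _mutate_stem(rng: random.Random, s5: str, s3: str, rate: float, lock5: int = 0):
    """Compensatory point mutations; the first ``lock5`` pairs are kept."""
    s5l, s3l = list(s5), list(s3)
    n = len(s5l)
    for i in range(lock5, n):
        if rng.random() < rate:
            base = rng.choice(P.DNA)
            s5l[i] = base
            s3l[n - 1 - i] = P.WC[base]
    return "".join(s5l), "".join(s3l)


def _mutate_loop(rng: random.Random, chunk: str, start_pos: int, rate: float) -> str:
    out = list(chunk)
    for i, c in enumerate(out):
        if start_pos + i in _PROTECTED:
            continue
        if rng.random() < rate:
            out[i] = rng.choice(P.DNA)
    return "".join(out)


def _make_record_parts(rng: random.Random, group: int, rate: float) -> Dict[str, str]:
    bb = group_backbone(group)
    parts: Dict[str, str] = {}
    a5, a3 = bb["acceptor_stem"].split(P.SEP)
    a5, a3 = _mutate_stem(rng, a5, a3, rate, lock5=3)  # keep the 1-3 signature
    parts["acceptor_stem"] = a5 + P.SEP + a3
    for name, lock in (("d_arm", 0), ("ac_stem", 0), ("t_arm", 0)):
        s5, s3 = bb[name].split(P.SEP)
        s5, s3 = _mutate_stem(rng, s5, s3, rate, lock5=lock)
        parts[name] = s5 + P.SEP + s3
    parts["unpaired_8_9"] = _mutate_loop(rng, bb["unpaired_8_9"], 8, rate)
    dloop, tloop = bb["dt_loops"].split(P.SEP)
    dloop = _mutate_loop(rng, dloop, 14, rate)
    tloop = _mutate_loop(rng, tloop, 54, rate)
    parts["dt_loops"] = dloop + P.SEP + tloop
    b26, vl = bb["vloop"].split(P.SEP)
    vl = _mutate_loop(rng, vl, 44, rate)
    if rng.random() < 0.3:  # natural loop-length variation
        vl = vl[: rng.choice((3, 4))]
    parts["vloop"] = _mutate_loop(rng, b26, 26, rate) + P.SEP + vl
    parts["ac_loop"] = _mutate_loop(rng, bb["ac_loop"], 32, rate)
    parts["disc_cca"] = bb["disc_cca"]
    return parts


def _shorten_dloop(rng: random.Random, parts: Dict[str, str]) -> None:
    """Emit a benign 6-7 nt D-loop that the GG heuristic can re-align.

    Bases immediately 5' of the GG motif are dropped, so re-alignment
    re-inserts gaps exactly where the bases were removed.
    """
    dloop, tloop = parts["dt_loops"].split(P.SEP)
    if rng.random() < 0.5:
        short = dloop[:3] + dloop[4:]  # 7 nt
    else:
        short = dloop[:2] + dloop[4:]  # 6 nt
    parts["dt_loops"] = short + P.SEP + tloop


def _corrupt(rng: random.Random, row: Dict[str, str], kind: str) -> None:
    if kind == "missing_field":
        row[rng.choice(("organism", "isoacceptor", "anticodon"))] = ""
    elif kind == "ambiguous_base":
        tloop = row["dt_loops"].split(P.SEP)[1]
        i = rng.randrange(len(tloop))
        row["dt_loops"] = (
            row["dt_loops"].split(P.SEP)[0]
            + P.SEP
            + tloop[:i]
            + rng.choice("NRYWS")
            + tloop[i + 1 :]
        )
    elif kind == "bad_dloop":
        # eight nucleotides, no GG at the canonical slots (or anywhere)
        row["dt_loops"] = "ATCTCTCA" + P.SEP + row["dt_loops"].split(P.SEP)[1]
    else:  # pragma: no cover
        raise ValueError(kind)


_CORRUPTION_KINDS = ("missing_field", "ambiguous_base", "bad_dloop")


def make_db(config: SynthConfig) -> Tuple[pd.DataFrame, Dict]:
    """Build a raw database table and its ground-truth manifest."""
    rng = random.Random(config.seed)
    rows: List[Dict[str, str]] = []
    manifest: Dict = {
        "config": {
            "n_organisms": config.n_organisms,
            "isoacceptors": list(config.isoacceptors),
            "mutation_rate": config.mutation_rate,
            "corruption_rate": config.corruption_rate,
            "n_identity_groups": config.n_identity_groups,
            "seed": config.seed,
        },
        "records": {},
    }
    for org_idx in range(config.n_organisms):
        organism = f"organism_{org_idx:04d}"
        group = org_idx % config.n_identity_groups
        for iso in config.isoacceptors:
            gene_id = f"{iso}_{org_idx:04d}"
            parts = _make_record_parts(rng, group, config.mutation_rate)
            # Short D-loops gap out canonical position 16, so host-like
            # (group 0) records keep full-length loops to preserve their
            # exact identity-table match.
            short_dloop = group > 0 and rng.random() < config.short_dloop_rate
            if short_dloop:
                _shorten_dloop(rng, parts)
            row = {
                "gene_id": gene_id,
                "organism": organism,
                "isoacceptor": iso,
                "anticodon": P.get_anticodon(parts),
                **parts,
            }
            corruption: Optional[str] = None
            if rng.random() < config.corruption_rate:
                corruption = rng.choice(_CORRUPTION_KINDS)
                _corrupt(rng, row, corruption)
            rows.append(row)
            manifest["records"][gene_id] = {
                "organism": organism,
                "isoacceptor": iso,
                "group": group,
                "host_like": group == 0,
                "corruption": corruption,
                "short_dloop": short_dloop,
            }
    df = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))
    return df, manifest


def make_identity_table(config: SynthConfig) -> IdentityTable:
    """A host identity table consistent with the planted groups.

    Group-0 (host-like) records match it at every element position;
    foreign-group records mismatch at the planted signature positions
    and score at or below zero under the sequence identity score.
    """
    if not config.isoacceptors:
        raise ValueError("no isoacceptors configured")
    host = HOST_BACKBONE
    a5, a3 = host["acceptor_stem"].split(P.SEP)
    dloop, tloop = host["dt_loops"].split(P.SEP)
    bases: Dict[int, str] = {
        1: a5[0],
        2: a5[1],
        3: a5[2],
        70: a3[4],
        71: a3[5],
        72: a3[6],
        73: host["disc_cca"][0],
        14: dloop[0],
        15: dloop[1],
        16: dloop[2],
        20: dloop[6],
        59: tloop[5],
        60: tloop[6],
    }
    genes = {
        iso: {f"host_{iso}": dict(bases)} for iso in config.isoacceptors
    }
    return IdentityTable(genes)


def write_synth_db(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
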