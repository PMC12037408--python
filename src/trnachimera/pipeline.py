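"""End-to-end chimera design runs with an audited manifest.

The stage chain mirrors how a design run proceeds: slice the cleaned
database to the target's isoacceptor class, fix the target's identity
parts, filter and score the variable parts, cluster them to exemplars,
stream the combinatorial chimera library, then prune it by length, host
sequence-identity stringency, cloverleaf folding for each requested
anticodon, and finally reduce the survivors to a small maximally diverse
output group.

Every stage appends its survivor count to the manifest; counts after
generation must be non-increasing, and the manifest records the seed,
the folding-engine version and the full configuration so a run can be
reproduced bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from . import engine as E
from . import parts as P
from . import select as S
from . import structure as ST
from .db import TrnaRecord
from .identity import (
    IdentityTable,
    fixed_part_positions,
    part_identity_score,
    sequence_identity_score,
)

log = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config: Dict
    seed: int
    engine: Tuple[str, str]
    counts: List[Tuple[str, int]] = field(default_factory=list)
    part_rejections: Dict[str, int] = field(default_factory=dict)
    stringency_final: Optional[float] = None
    prefilter_cutoff: Optional[int] = None
    selection_mode: Optional[str] = None
    input_checksum: Optional[str] = None
    started: float = 0.0
    finished: float = 0.0

    def add(self, stage: str, count: int) -> None:
        self.counts.append((stage, count))

    def check_monotone(self) -> None:
        """Counts after generation must never increase along the chain."""
        chain = [c for s, c in self.counts if s != "input"]
        for a, b in zip(chain, chain[1:]):
            if b > a:
                raise AssertionError(f"count chain not monotone: {self.counts}")

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        payload["engine"] = list(self.engine)
        return json.dumps(payload, indent=2)


@dataclass
class RunResult:
    designs: List[E.ChimeraDesign]
    selection: Optional[S.SelectionResult]
    manifest: RunManifest
    design_by_seq: Dict[str, E.ChimeraDesign] = field(default_factory=dict)


def checksum_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    records: Sequence[TrnaRecord],
    config: E.RunConfig,
    table: IdentityTable,
    spec: ST.CloverleafSpec = ST.CloverleafSpec(),
    input_checksum: Optional[str] = None,
) -> RunResult:
    manifest = RunManifest(
        config=dataclasses.asdict(config),
        seed=config.seed,
        engine=ST.ENGINE,
        input_checksum=input_checksum,
        started=time.time(),
    )
    iso = [r for r in records if r.isoacceptor == config.isoacceptor]
    manifest.add("input", len(iso))
    target = next((r for r in iso if r.gene_id == config.target_gene_id), None)
    if target is None:
        raise ValueError(
            f"target {config.target_gene_id!r} not found in isoacceptor "
            f"class {config.isoacceptor!r}"
        )

    fixed = {
        name: E.PartChoice.make(name, target.parts[name], target.gene_id)
        for name in config.fixed_parts
    }
    variable_names = [n for n in P.PART_NAMES if n not in config.fixed_parts]
    pools: Dict[str, List[E.PartChoice]] = {
        name: [
            E.PartChoice.make(name, r.parts[name], r.gene_id)
            for r in iso
            if r.gene_id != target.gene_id
        ]
        for name in variable_names
    }
    kept, rejected = E.filter_parts(pools)
    manifest.part_rejections = {f"{p}:{rule}": n for (p, rule), n in rejected.items()}

    scored: Dict[str, List[Tuple[E.PartChoice, float]]] = {}
    score_cache: Dict[Tuple[str, str], float] = {}
    for name in variable_names:
        entries = []
        for c in kept[name]:
            key = (name, c.seq)
            if key not in score_cache:
                score_cache[key] = part_identity_score(name, c.seq, table).score
            entries.append((c, score_cache[key]))
        scored[name] = entries

    designs, libraries = E.run_iterations(scored, fixed, config)
    manifest.add("generated", len(designs))

    stats: Counter = Counter()
    designs = list(E.length_filter(designs, config.length_filt, stats))
    manifest.add("length", len(designs))

    excluded = fixed_part_positions(config.fixed_parts)
    scored_designs = []
    for d in designs:
        vec = sequence_identity_score(d.parts(), table, excluded)
        if not vec.scores:
            d.audit.append("no-scorable-elements")
            continue
        d.score = vec
        scored_designs.append(d)
    survivors, final_t = E.stringency_filter(
        scored_designs,
        config.stringency_start,
        config.stringency_min,
        config.stringency_target,
        config.stringency_step,
    )
    manifest.stringency_final = final_t
    manifest.add("identity", len(survivors))

    first_ac = config.anticodons[0]
    survivors = ST.mfe_filter(
        survivors, first_ac, config.frequency, config.diversity, spec
    )
    manifest.add(f"cloverleaf@{first_ac}", len(survivors))
    survivors, sweep_counts = ST.anticodon_sweep(
        survivors,
        config.anticodons,
        config.frequency,
        config.diversity,
        config.final_frequency,
        config.final_diversity,
        spec,
    )
    for ac, n in zip(config.anticodons[1:], sweep_counts):
        manifest.add(f"cloverleaf@{ac}", n)
    manifest.add("ensemble", sweep_counts[-1])

    by_seq = {d.assembled(): d for d in survivors}
    seqs = sorted(by_seq)
    if config.automatic or config.mismatch_threshold is not None:
        parent_seq = target.assembled()
        seqs, cutoff = S.mismatch_prefilter(
            seqs, parent_seq, cap=200, hard_threshold=config.mismatch_threshold
        )
        manifest.prefilter_cutoff = cutoff
    manifest.add("prefilter", len(seqs))

    selection: Optional[S.SelectionResult] = None
    if seqs:
        exemplar_idx = S.cluster_candidates(seqs, seed=config.seed)
        exemplars = [seqs[i] for i in exemplar_idx]
        manifest.add("exemplars", len(exemplars))
        k = min(config.num_trnas, len(exemplars))
        if k < config.num_trnas:
            log.warning(
                "only %d exemplars available for a group of %d",
                len(exemplars),
                config.num_trnas,
            )
        selection = S.pick_diverse_group(exemplars, k, seed=config.seed)
        manifest.selection_mode = selection.mode
        manifest.add("final", len(selection.chosen))
        final_designs = [by_seq[s] for s in selection.chosen]
    else:
        manifest.add("exemplars", 0)
        manifest.add("final", 0)
        final_designs = []

    manifest.finished = time.time()
    manifest.check_monotone()
    return RunResult(final_designs, selection, manifest, by_seq)
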