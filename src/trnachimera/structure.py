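"""Thermodynamic folding and cloverleaf structure filtering.

Sequences are folded with the ViennaRNA library at its default parameters
(37 degC, partition function enabled).  Three ensemble statistics are
extracted for each sequence:

* the minimum free energy (MFE) structure and its energy,
* the **frequency**: the MFE structure's percentage share of the
  Boltzmann ensemble, exp((G_ensemble - E_MFE) / RT) * 100,
* the **ensemble diversity**: the mean base-pair distance between
  structures in the ensemble (delta-bp).

The MFE dot-bracket is then matched against a configurable cloverleaf
grammar (acceptor stem, D-arm, anticodon arm with the anticodon triplet
unpaired, variable loop, T-arm).  The default grammar accepts small
deviations — extra pairing inside the variable loop or involving the 8-9
linker, and partial pairing of the D-loop — the latter only when the
sequence keeps a U in the 8-9 linker and an A opening the D-loop.  The
grammar is a reconstruction expressed as ranges and compiled to a regular
expression; every tolerance can be switched off.

Survival filters are inclusive: a chimera survives when its structure is
cloverleaf, frequency >= the threshold and diversity <= the threshold.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from statistics import mean
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from scipy.stats import fisher_exact

from . import parts as P

try:  # pragma: no cover - import guard exercised only without ViennaRNA
    import RNA

    ENGINE = ("ViennaRNA", RNA.__version__)
except ImportError:  # pragma: no cover
    RNA = None
    ENGINE = ("ViennaRNA", "unavailable")

log = logging.getLogger(__name__)


def _require_engine() -> None:
    if RNA is None:  # pragma: no cover
        raise RuntimeError(
            "the ViennaRNA Python bindings are required for folding; "
            "install the 'viennarna' package"
        )


@dataclass
class FoldResult:
    sequence: str  # RNA alphabet, as folded
    mfe_structure: str
    mfe_energy: float  # kcal/mol
    ensemble_energy: float  # kcal/mol
    frequency: float  # percent of the ensemble
    diversity: float  # mean base-pair distance
    engine: Tuple[str, str] = ENGINE
    is_cloverleaf: Optional[bool] = None
    reasons: Tuple[str, ...] = ()


def fold(sequence: str) -> FoldResult:
    """Fold a DNA/RNA sequence and extract MFE ensemble statistics."""
    _require_engine()
    rna = sequence.upper().replace("T", "U")
    if any(c not in "ACGU" for c in rna):
        raise ValueError(f"cannot fold non-nucleotide sequence: {sequence!r}")
    fc = RNA.fold_compound(rna)
    ss, mfe = fc.mfe()
    fc.exp_params_rescale(mfe)
    _, dg = fc.pf()
    freq = fc.pr_structure(ss) * 100.0
    div = fc.mean_bp_distance()
    return FoldResult(
        sequence=rna,
        mfe_structure=ss,
        mfe_energy=float(mfe),
        ensemble_energy=float(dg),
        frequency=float(freq),
        diversity=float(div),
    )


def boltzmann_frequency(result: FoldResult) -> float:
    """Recompute the MFE frequency from the reported energies (percent)."""
    _require_engine()
    kt = RNA.exp_param().kT / 1000.0  # kcal/mol at default 37 degC
    return math.exp((result.ensemble_energy - result.mfe_energy) / kt) * 100.0


# ---------------------------------------------------------------------------
# Cloverleaf classification


@dataclass(frozen=True)
class CloverleafSpec:
    """Structural grammar for an acceptable cloverleaf dot-bracket.

    Ranges are (min, max) inclusive; stems in base pairs, loops in
    unpaired bases.  Tolerance switches admit small deviations seen in
    otherwise-functional tRNAs.
    """

    acceptor_stem: Tuple[int, int] = (6, 7)
    link_8_9: Tuple[int, int] = (1, 3)
    d_stem: Tuple[int, int] = (3, 4)
    d_loop: Tuple[int, int] = (3, 12)
    link_26: Tuple[int, int] = (0, 2)
    ac_stem: Tuple[int, int] = (4, 6)
    ac_loop: Tuple[int, int] = (7, 9)
    vloop: Tuple[int, int] = (1, 9)
    t_stem: Tuple[int, int] = (4, 6)
    t_loop: Tuple[int, int] = (6, 9)
    tail: Tuple[int, int] = (1, 6)
    allow_vloop_hairpin: bool = True
    allow_dloop_pairing: bool = True


def _rng(r: Tuple[int, int], ch: str) -> str:
    return rf"\{ch}{{{r[0]},{r[1]}}}"


def _strict_pattern(spec: CloverleafSpec) -> str:
    return (
        "^"
        + _rng(spec.acceptor_stem, "(")
        + _rng(spec.link_8_9, ".")
        + _rng(spec.d_stem, "(")
        + f"(?P<dloop>{_rng(spec.d_loop, '.')})"
        + _rng(spec.d_stem, ")")
        + _rng(spec.link_26, ".")
        + _rng(spec.ac_stem, "(")
        + _rng(spec.ac_loop, ".")
        + _rng(spec.ac_stem, ")")
        + f"(?P<vloop>{_rng(spec.vloop, '.')})"
        + _rng(spec.t_stem, "(")
        + _rng(spec.t_loop, ".")
        + _rng(spec.t_stem, ")")
        + _rng(spec.acceptor_stem, ")")
        + _rng(spec.tail, ".")
        + "$"
    )


def _vloop_hairpin_pattern(spec: CloverleafSpec) -> str:
    # A small self-contained hairpin inside the variable loop.
    hairpin = r"\.{0,4}\({1,3}\.{3,6}\){1,3}\.{0,4}"
    return _strict_pattern(spec).replace(
        f"(?P<vloop>{_rng(spec.vloop, '.')})", f"(?P<vloop>{hairpin})"
    )


def _dloop_paired_pattern(spec: CloverleafSpec) -> str:
    # Part of the D-loop pairs internally; only the flanks stay unpaired.
    paired = r"\.{1,5}\({1,3}\.{3,8}\){1,3}\.{0,5}"
    return _strict_pattern(spec).replace(
        f"(?P<dloop>{_rng(spec.d_loop, '.')})", f"(?P<dloop>{paired})"
    )


def classify_cloverleaf(
    structure: str,
    sequence: str,
    spec: CloverleafSpec = CloverleafSpec(),
) -> Tuple[bool, Tuple[str, ...]]:
    """Match an MFE dot-bracket against the cloverleaf grammar.

    A pure function of (structure, sequence, spec).  The D-loop-paired
    tolerance additionally requires the sequence to carry at least one
    U/T in the 8-9 linker and an A as the 5'-most D-loop base.
    """
    if len(structure) != len(sequence):
        raise ValueError("structure and sequence lengths differ")
    seq = sequence.upper().replace("U", "T")
    if re.fullmatch(_strict_pattern(spec)[1:-1], structure):
        return True, ("canonical",)
    if spec.allow_vloop_hairpin and re.fullmatch(
        _vloop_hairpin_pattern(spec)[1:-1], structure
    ):
        return True, ("vloop-hairpin",)
    if spec.allow_dloop_pairing:
        m = re.fullmatch(_dloop_paired_pattern(spec)[1:-1], structure)
        if m:
            # Auxiliary sequence rules gate this tolerance.
            acc_open = re.match(r"\(+", structure).end()
            link = seq[acc_open : acc_open + 2]
            dstart = seq[m.start("dloop")]
            if "T" in link and dstart == "A":
                return True, ("dloop-paired",)
            return False, ("dloop-paired-aux-failed",)
    return False, ("no-cloverleaf-match",)


def fold_and_classify(
    sequence: str, spec: CloverleafSpec = CloverleafSpec()
) -> FoldResult:
    result = fold(sequence)
    ok, reasons = classify_cloverleaf(result.mfe_structure, result.sequence, spec)
    return replace(result, is_cloverleaf=ok, reasons=reasons)


# ---------------------------------------------------------------------------
# Filters


def passes_mfe_filter(
    result: FoldResult, frequency_min: float, diversity_max: float
) -> bool:
    """Inclusive survival rule: cloverleaf, freq >= min, diversity <= max."""
    return bool(
        result.is_cloverleaf
        and result.frequency >= frequency_min
        and result.diversity <= diversity_max
    )


def mfe_filter(
    designs: Sequence,
    anticodon: str,
    frequency_min: float,
    diversity_max: float,
    spec: CloverleafSpec = CloverleafSpec(),
) -> List:
    """Fold each design with ``anticodon`` installed and keep survivors.

    Fold results are cached on the design's ``folds`` map keyed by
    anticodon; frequency thresholds are given as fractions (0.40 keeps
    frequency >= 40%).
    """
    kept = []
    for d in designs:
        if anticodon not in d.folds:
            d.folds[anticodon] = fold_and_classify(d.assembled(anticodon), spec)
        r = d.folds[anticodon]
        if passes_mfe_filter(r, frequency_min * 100.0, diversity_max):
            d.audit.append(f"cloverleaf@{anticodon}")
            kept.append(d)
    return kept


@dataclass
class EnsembleFoldResult:
    per_anticodon: Dict[str, FoldResult]
    mean_frequency: float
    mean_diversity: float
    passed: bool


def anticodon_sweep(
    designs: Sequence,
    anticodons: Sequence[str],
    frequency_min: float,
    diversity_max: float,
    final_frequency: float,
    final_diversity: Optional[float],
    spec: CloverleafSpec = CloverleafSpec(),
) -> Tuple[List, List[int]]:
    """Iteratively refold with each further anticodon, then apply the
    ensemble means.

    Per-anticodon survival uses the same inclusive rule as the first
    pass; the final cut drops any design whose mean frequency across all
    configured anticodons is below ``final_frequency`` or whose mean
    diversity exceeds ``final_diversity``.  Returns survivors and the
    count chain (one entry per anticodon pass, plus the final cut).
    """
    counts: List[int] = []
    current = list(designs)
    for ac in anticodons[1:]:
        current = mfe_filter(current, ac, frequency_min, diversity_max, spec)
        counts.append(len(current))
    survivors = []
    for d in current:
        folds = [d.folds[ac] for ac in anticodons]
        mf = mean(f.frequency for f in folds)
        md = mean(f.diversity for f in folds)
        ok = mf >= final_frequency * 100.0 and (
            final_diversity is None or md <= final_diversity
        )
        d.ensemble = EnsembleFoldResult(
            {ac: d.folds[ac] for ac in anticodons}, mf, md, ok
        )
        if ok:
            d.audit.append("ensemble")
            survivors.append(d)
    counts.append(len(survivors))
    return survivors, counts


# ---------------------------------------------------------------------------
# Profiling and enrichment


def profile(
    entries: Iterable[Tuple[str, str]],
    groups: Optional[Mapping[str, str]] = None,
    spec: CloverleafSpec = CloverleafSpec(),
) -> List[Dict]:
    """Fold a set of (id, sequence) pairs into a per-sequence table.

    Per-sequence fold failures are logged and reported as error rows so
    the output always has one row per input.
    """
    rows: List[Dict] = []
    for name, seq in entries:
        row = {"id": name, "group": (groups or {}).get(name, "")}
        try:
            r = fold_and_classify(seq, spec)
        except Exception as exc:  # pragma: no cover - engine failures
            log.error("fold failed for %s: %s", name, exc)
            row.update(error=str(exc), cloverleaf=None)
            rows.append(row)
            continue
        row.update(
            structure=r.mfe_structure,
            energy=r.mfe_energy,
            frequency=r.frequency,
            diversity=r.diversity,
            cloverleaf=r.is_cloverleaf,
            reasons=";".join(r.reasons),
        )
        rows.append(row)
    return rows


def group_summary(rows: Sequence[Mapping]) -> Dict[str, Tuple[int, int]]:
    """Per group: (cloverleaf count, total)."""
    out: Dict[str, List[int]] = {}
    for row in rows:
        g = row.get("group", "")
        out.setdefault(g, [0, 0])
        out[g][1] += 1
        if row.get("cloverleaf"):
            out[g][0] += 1
    return {g: (c, n) for g, (c, n) in out.items()}


def enrichment_test(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value for a 2x2 contingency table."""
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("table entries must be non-negative integers")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return 1.0
    return float(fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
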