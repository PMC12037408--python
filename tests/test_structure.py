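"""Folding statistics, cloverleaf classification, filters and enrichment."""

import math
import random
from dataclasses import dataclass, field, replace

import pytest

from trnachimera import parts as P
from trnachimera.structure import (
    CloverleafSpec,
    FoldResult,
    anticodon_sweep,
    boltzmann_frequency,
    classify_cloverleaf,
    enrichment_test,
    fold,
    fold_and_classify,
    group_summary,
    passes_mfe_filter,
    profile,
)
from trnachimera.synth import HOST_BACKBONE

BACKBONE_SEQ = P.assemble(HOST_BACKBONE)


class TestFold:
    def test_frequency_satisfies_boltzmann_identity(self):
        r = fold(BACKBONE_SEQ)
        assert 0 < r.frequency <= 100
        assert r.diversity >= 0
        assert abs(r.frequency - boltzmann_frequency(r)) < 0.1

    def test_structure_is_balanced_and_same_length(self):
        r = fold(BACKBONE_SEQ)
        assert len(r.mfe_structure) == len(BACKBONE_SEQ)
        depth = 0
        for c in r.mfe_structure:
            depth += {"(": 1, ")": -1}.get(c, 0)
            assert depth >= 0
        assert depth == 0

    def test_dna_input_is_folded_as_rna(self):
        r = fold(BACKBONE_SEQ)
        assert "T" not in r.sequence and "U" in r.sequence

    def test_non_nucleotide_input_is_an_error(self):
        with pytest.raises(ValueError):
            fold("ACGTN" * 10)

    def test_engine_version_is_recorded(self):
        r = fold(BACKBONE_SEQ)
        assert r.engine[0] == "ViennaRNA" and r.engine[1]


CANONICAL = (
    "(((((((..((((........)))).(((((.......))))).....(((((.......))))))))))))...."
)


class TestCloverleaf:
    def test_canonical_structure_accepted(self):
        ok, reasons = classify_cloverleaf(CANONICAL, "A" * 76)
        assert ok and reasons == ("canonical",)

    def test_backbone_folds_into_cloverleaf(self):
        r = fold_and_classify(BACKBONE_SEQ)
        assert r.is_cloverleaf

    def test_paired_anticodon_rejected(self):
        # anticodon arm folded into one long helix covering 34-36
        s = "(((((((..((((........)))).((((((((...)))))))).....((((.......)))))))))))...."
        assert len(s) == 76
        ok, _ = classify_cloverleaf(s, "A" * 76)
        assert not ok

    def test_linear_structure_rejected(self):
        ok, reasons = classify_cloverleaf("." * 76, "A" * 76)
        assert not ok

    def test_dloop_pairing_tolerance_gated_on_sequence_rules(self):
        s = "(((((((..((((.((...)).)))).(((((.......))))).....(((((.......))))))))))))...."
        seq_ok = list("G" * len(s))
        seq_ok[7:9] = "TA"  # U in the 8-9 linker
        seq_ok[13] = "A"  # D-loop opens with A
        ok, reasons = classify_cloverleaf(s, "".join(seq_ok))
        assert ok and reasons == ("dloop-paired",)
        seq_bad = list(seq_ok)
        seq_bad[7:9] = "AA"
        ok2, reasons2 = classify_cloverleaf(s, "".join(seq_bad))
        assert not ok2 and reasons2 == ("dloop-paired-aux-failed",)

    def test_classification_is_deterministic(self):
        for _ in range(3):
            assert classify_cloverleaf(CANONICAL, "A" * 76) == classify_cloverleaf(
                CANONICAL, "A" * 76
            )

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            classify_cloverleaf("...", "ACGT")


def _fr(freq, div, clover=True):
    return FoldResult(
        sequence="A",
        mfe_structure=".",
        mfe_energy=0.0,
        ensemble_energy=0.0,
        frequency=freq,
        diversity=div,
        is_cloverleaf=clover,
    )


class TestMfeFilter:
    def test_inclusive_boundaries(self):
        assert passes_mfe_filter(_fr(40.0, 9.0), 40.0, 9.0)
        assert not passes_mfe_filter(_fr(39.9, 5.0), 40.0, 9.0)
        assert not passes_mfe_filter(_fr(90.0, 1.0, clover=False), 40.0, 9.0)

    def test_monotone_in_both_thresholds(self):
        r = _fr(55.0, 6.0)
        assert passes_mfe_filter(r, 50.0, 7.0)
        assert not passes_mfe_filter(r, 60.0, 7.0)
        assert not passes_mfe_filter(r, 50.0, 5.0)


@dataclass
class _StubDesign:
    folds: dict
    audit: list = field(default_factory=list)
    ensemble: object = None


class TestSweep:
    def test_single_anticodon_sweep_is_identity_on_survivors(self):
        d = _StubDesign({"CTA": _fr(60.0, 3.0)})
        out, counts = anticodon_sweep([d], ["CTA"], 0.4, 9.0, 0.5, 8.0)
        assert out == [d] and counts == [1]

    def test_final_cut_uses_arithmetic_means(self):
        freqs = (60.0, 55.0, 20.0)
        d = _StubDesign({ac: _fr(f, 2.0) for ac, f in zip(["CTA", "TGA", "CGA"], freqs)})
        out, _ = anticodon_sweep([d], ["CTA", "TGA", "CGA"], 0.1, 9.0, 0.5, 8.0)
        assert out == []  # mean 45% < 50%
        assert d.ensemble.mean_frequency == pytest.approx(45.0)
        d2 = _StubDesign({ac: _fr(f + 10, 2.0) for ac, f in zip(["CTA", "TGA", "CGA"], freqs)})
        out2, _ = anticodon_sweep([d2], ["CTA", "TGA", "CGA"], 0.1, 9.0, 0.5, 8.0)
        assert out2 == [d2]

    def test_per_anticodon_failure_removes_design(self):
        d = _StubDesign({"CTA": _fr(60.0, 3.0), "TGA": _fr(60.0, 3.0, clover=False)})
        out, counts = anticodon_sweep([d], ["CTA", "TGA"], 0.4, 9.0, 0.0, None)
        assert out == [] and counts == [0, 0]


class TestProfile:
    def test_robust_set_is_all_cloverleaf(self):
        entries = [(f"s{i}", BACKBONE_SEQ) for i in range(5)]
        rows = profile(entries)
        assert len(rows) == 5
        assert all(r["cloverleaf"] for r in rows)

    def test_rows_are_auditable_by_reclassification(self):
        rng = random.Random(23)
        entries = []
        for i in range(10):
            shuffled = list(BACKBONE_SEQ)
            rng.shuffle(shuffled)
            entries.append((f"shuf{i}", "".join(shuffled)))
        rows = profile(entries)
        for row in rows:
            seq = dict(entries)[row["id"]]
            ok, _ = classify_cloverleaf(row["structure"], seq)
            assert ok == row["cloverleaf"]

    def test_group_counts_sum_to_set_size(self):
        entries = [(f"s{i}", BACKBONE_SEQ) for i in range(6)]
        groups = {f"s{i}": ["NO", "OA", "U"][i % 3] for i in range(6)}
        rows = profile(entries, groups)
        summary = group_summary(rows)
        assert sum(n for _, n in summary.values()) == 6


def _fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def log_fact(k):
        return math.lgamma(k + 1)

    def log_p(x):
        return (
            log_fact(r1)
            + log_fact(r2)
            + log_fact(c1)
            + log_fact(n - c1)
            - log_fact(n)
            - log_fact(x)
            - log_fact(r1 - x)
            - log_fact(c1 - x)
            - log_fact(r2 - c1 + x)
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = log_p(a)
    total = 0.0
    for x in range(lo, hi + 1):
        lp = log_p(x)
        if lp <= p_obs + 1e-9:
            total += math.exp(lp)
    return min(total, 1.0)


class TestEnrichment:
    def test_equal_proportions_give_p_one(self):
        assert enrichment_test([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_degenerate_margins_give_p_one(self):
        assert enrichment_test([[1, 0], [0, 0]]) == 1.0
        assert enrichment_test([[0, 0], [0, 0]]) == 1.0

    def test_perfect_separation_matches_enumeration(self):
        assert enrichment_test([[10, 0], [0, 10]]) == pytest.approx(
            _fisher_oracle(10, 0, 0, 10)
        )

    def test_matches_enumeration_oracle_for_small_tables(self):
        rng = random.Random(31)
        for _ in range(60):
            a, b, c, d = (rng.randint(0, 10) for _ in range(4))
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            assert enrichment_test([[a, b], [c, d]]) == pytest.approx(
                _fisher_oracle(a, b, c, d), rel=1e-9
            )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            enrichment_test([[1, -1], [0, 2]])
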