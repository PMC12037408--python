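"""Part filtering, exemplar selection, combinatorial generation, filters."""

import random
from itertools import islice

import pytest

from trnachimera import parts as P
from trnachimera.engine import (
    ChimeraDesign,
    PartChoice,
    RunConfig,
    count_chimeras,
    crtm_generate,
    filter_parts,
    generate_chimeras,
    length_filter,
    load_schemes,
    part_passes,
    run_iterations,
    select_exemplars,
    stringency_filter,
)
from trnachimera.identity import SeqScoreVector
from trnachimera.synth import HOST_BACKBONE

from conftest import make_record


def pc(name, seq, source="src"):
    return PartChoice.make(name, seq, source)


class TestPartRules:
    def test_watson_crick_paired_part_kept(self):
        assert part_passes("d_arm", "GCTA_TAGC") is None

    def test_single_wobble_pair_rejected(self):
        # G.T is a wobble pair; the part filter is strict Watson-Crick.
        assert part_passes("d_arm", "GCTG_TAGC") == "watson-crick"

    def test_unpaired_8_9_requires_a_uracil(self):
        assert part_passes("unpaired_8_9", "AA") == "no-uracil-8-9"
        assert part_passes("unpaired_8_9", "TA") is None

    def test_dloop_must_start_with_adenine(self):
        assert part_passes("dt_loops", "GACTGGCA_TTCGAGC") == "dloop-start"

    def test_variable_loop_shorter_than_8(self):
        assert part_passes("vloop", "A_TTTCTTT") is None  # 7 nt loop
        assert part_passes("vloop", "A_TTTCTTTT") == "vloop-length"  # 8 nt

    def test_ambiguity_codes_rejected(self):
        assert part_passes("unpaired_8_9", "TN") == "alphabet"

    def test_filter_parts_counts_every_failure(self):
        pools = {
            "d_arm": [pc("d_arm", "GCTA_TAGC"), pc("d_arm", "GCTG_TAGC")],
            "unpaired_8_9": [pc("unpaired_8_9", "AA")],
        }
        kept, rejected = filter_parts(pools)
        assert [c.seq for c in kept["d_arm"]] == ["GCTA_TAGC"]
        assert rejected[("d_arm", "watson-crick")] == 1
        assert rejected[("unpaired_8_9", "no-uracil-8-9")] == 1


class TestExemplars:
    def test_small_pools_returned_unclustered(self):
        seqs = ("TA", "TT", "TC", "TG", "AT", "CT")
        scored = [(pc("unpaired_8_9", s), 0.1) for s in seqs]
        out = select_exemplars(scored, top_n=200, min_cluster_size=15)
        assert sorted(c.seq for c in out) == sorted(seqs)

    def test_identical_sequences_collapse_to_one(self):
        scored = [(pc("d_arm", "GCTA_TAGC", f"s{i}"), 0.0) for i in range(20)]
        out = select_exemplars(scored, top_n=200, min_cluster_size=1)
        assert len(out) == 1

    def test_exemplars_cover_both_distance_blobs(self):
        rng = random.Random(11)

        def blob(base, n):
            out = set()
            while len(out) < n:
                s = list(base)
                i = rng.randrange(len(s))
                s[i] = rng.choice("ACGT")
                out.add("".join(s))
            return sorted(out)

        blob_a = blob("AAAAAAAAAAAAAAA", 15)
        blob_b = blob("GGGGGGGGGGGGGGG", 15)
        scored = [(pc("ac_loop", s[:7]), 0.0) for s in blob_a + blob_b]
        # 7-mers: rebuild blobs on the truncated sequences
        seqs = {c.seq for c, _ in scored}
        out = select_exemplars(scored, top_n=200, min_cluster_size=2, seed=0)
        got_a = any(c.seq.startswith("A") or c.seq.count("A") >= 4 for c in out)
        got_b = any(c.seq.count("G") >= 4 for c in out)
        assert 2 <= len(out) <= len(seqs)
        assert got_a and got_b

    def test_top_n_takes_lowest_scores_with_lexicographic_ties(self):
        scored = [
            (pc("ac_loop", "CTCTAAA"), 0.5),
            (pc("ac_loop", "ATCTAAA"), 0.1),
            (pc("ac_loop", "GTCTAAA"), 0.1),
            (pc("ac_loop", "TTCTAAA"), 0.9),
        ]
        out = select_exemplars(scored, top_n=2, min_cluster_size=15)
        assert [c.seq for c in out] == ["ATCTAAA", "GTCTAAA"]


def library_of_sizes(sizes):
    """Distinct part variants per slot, derived from the consensus backbone.

    Mutated positions avoid the anticodon (overwritten at generation
    time), so variant counts survive assembly and deduplication.
    """
    lib = {}
    for name, n in zip(P.PART_NAMES, sizes):
        base = HOST_BACKBONE[name]
        if name == "ac_loop":
            mutable = [0, 1, 5]
        else:
            mutable = [i for i, ch in enumerate(base) if ch != "_"][:3]
        variants = []
        for combo in _letter_combos():
            s = list(base)
            for i, ch in zip(mutable, combo):
                s[i] = ch
            v = "".join(s)
            if v not in {x.seq for x in variants}:
                variants.append(pc(name, v, f"{name}{len(variants)}"))
            if len(variants) == n:
                break
        lib[name] = variants
    return lib


def _letter_combos():
    from itertools import product

    return product("ACGT", repeat=3)


class TestGeneration:
    def test_all_singletons_yield_exactly_one(self):
        lib = library_of_sizes([1] * 9)
        assert [d.assembled() for d in generate_chimeras(lib, "CTA")]
        assert count_chimeras(lib) == 1

    def test_two_by_two_enumeration(self):
        sizes = [1, 2, 1, 1, 1, 2, 1, 1, 1]
        lib = library_of_sizes(sizes)
        designs = list(generate_chimeras(lib, "CTA"))
        assert len(designs) == 4
        assert len({d.assembled() for d in designs}) == 4

    def test_streamed_count_matches_product_for_random_sizes(self):
        rng = random.Random(13)
        for _ in range(10):
            sizes = [rng.randint(1, 3) for _ in range(9)]
            lib = library_of_sizes(sizes)
            n_stream = sum(1 for _ in generate_chimeras(lib, "CTA"))
            assert n_stream == count_chimeras(lib)

    def test_empty_slot_is_an_error_naming_the_part(self):
        lib = library_of_sizes([1] * 9)
        lib["t_arm"] = []
        with pytest.raises(ValueError, match="t_arm"):
            next(generate_chimeras(lib, "CTA"))

    def test_anticodon_is_installed_on_every_chimera(self):
        lib = library_of_sizes([1, 2, 1, 1, 1, 1, 2, 1, 1])
        for d in generate_chimeras(lib, "TGA"):
            assert P.get_anticodon(d.parts()) == "TGA"


class TestLengthFilter:
    def test_inclusive_boundary_below_79(self):
        lib = library_of_sizes([1] * 9)
        d78 = next(generate_chimeras(lib, "CTA"))
        assert d78.length == 76
        assert list(length_filter([d78], 79)) == [d78]

    def test_79_nt_dropped(self):
        lib = library_of_sizes([1] * 9)
        d = next(generate_chimeras(lib, "CTA"))
        assert list(length_filter([d], 76)) == []  # 76 is not < 76

    def test_empty_stream(self):
        assert list(length_filter([], 79)) == []


def _design_with_score(lib_design, score):
    lib_design.score = SeqScoreVector({"Ala": score})
    return lib_design


class TestStringency:
    def _designs(self, scores):
        lib = library_of_sizes([1, 1, 1, 1, 4, 2, 1, 1, 1])
        designs = list(islice(generate_chimeras(lib, "CTA"), len(scores)))
        assert len(designs) == len(scores)
        return [_design_with_score(d, s) for d, s in zip(designs, scores)]

    def test_threshold_walks_down_to_satisfy_target(self):
        designs = self._designs([0.6, 0.45, 0.2, 0.0, -0.1])
        kept, t = stringency_filter(designs, 0.5, 0.0, 2, 0.05)
        assert sorted(d.score.max_score for d in kept) == [-0.1, 0.0]

    def test_all_nonpositive_scores_kept_at_start(self):
        designs = self._designs([0.0, -0.2, -0.5])
        kept, t = stringency_filter(designs, 0.5, 0.0, 10, 0.05)
        assert len(kept) == 3 and t == 0.5

    def test_target_zero_stops_at_floor_keeping_scores_at_minimum(self):
        designs = self._designs([0.3, 0.0, -0.1])
        kept, t = stringency_filter(designs, 0.5, 0.0, 0, 0.05)
        assert t == pytest.approx(0.0)
        assert sorted(d.score.max_score for d in kept) == [-0.1, 0.0]

    def test_monotone_in_threshold(self):
        designs = self._designs([0.5, 0.4, 0.3, 0.1, -0.2])
        lower, _ = stringency_filter(designs, 0.2, 0.2, 10**6, 0.05)
        higher, _ = stringency_filter(designs, 0.45, 0.45, 10**6, 0.05)
        assert {id(d) for d in lower} <= {id(d) for d in higher}


class TestIterations:
    def _scored(self, n_per_part):
        lib = library_of_sizes([1] + [n_per_part] * 7 + [1])
        fixed = {
            "acceptor_stem": lib["acceptor_stem"][0],
            "disc_cca": lib["disc_cca"][0],
        }
        scored = {
            name: [(c, 0.0) for c in lib[name]]
            for name in P.PART_NAMES
            if name not in fixed
        }
        return scored, fixed

    def test_single_iteration_equals_single_pass(self):
        scored, fixed = self._scored(2)
        cfg = RunConfig("t", "Trp", cluster_parts=10, min_cluster_size=50, seed=1)
        designs, libs = run_iterations(scored, fixed, cfg)
        assert len(libs) == 1
        assert len(designs) == 2**7

    def test_iterations_use_disjoint_exemplars(self):
        scored, fixed = self._scored(3)
        cfg = RunConfig(
            "t", "Trp", cluster_parts=1, min_cluster_size=50, num_iterations=3, seed=1
        )
        designs, libs = run_iterations(scored, fixed, cfg)
        assert len(libs) == 3
        for name in scored:
            used = [frozenset(c.seq for c in lib[name]) for lib in libs]
            assert not (used[0] & used[1]) and not (used[1] & used[2])

    def test_exhausted_pool_stops_early(self):
        scored, fixed = self._scored(1)
        cfg = RunConfig(
            "t", "Trp", cluster_parts=5, min_cluster_size=50, num_iterations=2, seed=1
        )
        designs, libs = run_iterations(scored, fixed, cfg)
        assert len(libs) == 1  # second iteration had nothing left


class TestCrtm:
    def _family(self, n_donors):
        parent = make_record(gene_id="parent")
        donors = []
        for i in range(n_donors):
            d = make_record(gene_id=f"donor{i}", vloop=f"A_TTT{'ACGT'[i % 4]}T")
            donors.append(d)
        return parent, donors

    def test_16_schemes_by_12_donors_gives_192(self):
        parent, donors = self._family(12)
        chimeras = crtm_generate(parent, donors, load_schemes())
        assert len(load_schemes()) == 16
        assert len(chimeras) == 192

    def test_empty_scheme_copies_the_parent(self):
        parent, donors = self._family(1)
        out = crtm_generate(parent, donors, [{"name": "noop", "parts": []}])
        assert out[0].parts == parent.parts

    def test_replacement_touches_only_scheme_regions(self):
        parent, donors = self._family(3)
        scheme = [{"name": "v", "parts": ["vloop"]}]
        out = crtm_generate(parent, donors, scheme)
        assert len(out) == 3
        for chim, donor in zip(out, donors):
            assert chim.parts["vloop"] == donor.parts["vloop"]
            for name in P.PART_NAMES:
                if name != "vloop":
                    assert chim.parts[name] == parent.parts[name]

    def test_donor_missing_region_is_skipped(self):
        parent, donors = self._family(2)
        donors[0].parts["vloop"] = ""
        out = crtm_generate(parent, donors, [{"name": "v", "parts": ["vloop"]}])
        assert len(out) == 1

    def test_wrong_isoacceptor_donor_is_skipped(self):
        parent, donors = self._family(2)
        donors[1].isoacceptor = "Ala"
        out = crtm_generate(parent, donors, [{"name": "v", "parts": ["vloop"]}])
        assert len(out) == 1
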