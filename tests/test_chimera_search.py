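import random

import pytest

from clashkit.chimera_search import (
    SearchParams,
    build_index,
    find_fragments_aligned,
    find_fragments_exact,
    pair_fragments,
    search_exhaustive,
    search_scored,
    search_strict,
)
from clashkit.io_formats import Read, SequenceSet
from _oracles import brute_force_fragments
from conftest import make_library, run_search


def rd(seq, read_id="r"):
    return Read(read_id, seq, [40] * len(seq))


def seq_set(role, **entries):
    return SequenceSet(role=role, names=list(entries), sequences=dict(entries))


def random_rna(rng, n):
    return "".join(rng.choice("ACGU") for _ in range(n))


class TestBuildIndex:
    def test_kmer_maps_to_all_offsets(self):
        index = build_index(seq_set("target", a="ACGUACGU"), k=4)
        assert index.lookup("ACGU") == [("a", 0), ("a", 4)]

    def test_absent_kmer_gives_empty_list(self):
        index = build_index(seq_set("target", a="ACGUACGU"), k=4)
        assert index.lookup("GGGG") == []

    def test_shared_kmer_lists_both_references(self):
        index = build_index(seq_set("target", a="AAACGUAAAC", b="CCACGUCCAC"), k=4)
        assert set(index.lookup("ACGU")) == {("a", 2), ("b", 2)}

    def test_reference_shorter_than_k_is_error(self):
        with pytest.raises(ValueError, match="shorty"):
            build_index(seq_set("target", shorty="ACG"), k=4)


class TestFindFragmentsExact:
    def test_full_reference_copy_found(self):
        refs = seq_set("regulatory", m="UCCCUGAGACCUCAAGUGUGA")
        index = build_index(refs, k=12)
        hits = find_fragments_exact(rd(refs["m"]), index, min_fragment_len=16)
        assert [(h.ref_name, h.read_span, h.ref_span) for h in hits] == [("m", (0, 21), (0, 21))]

    def test_short_shared_substring_below_minimum_ignored(self):
        rng = random.Random(5)
        core = random_rna(rng, 10)
        refs = seq_set("target", a=random_rna(rng, 15) + core + random_rna(rng, 15))
        index = build_index(refs, k=8)
        read = rd(random_rna(rng, 20) + core + random_rna(rng, 20))
        assert find_fragments_exact(read, index, min_fragment_len=16) == []

    def test_two_disjoint_copies_give_two_hits(self):
        rng = random.Random(6)
        ref = random_rna(rng, 40)
        refs = seq_set("target", a=ref)
        index = build_index(refs, k=12)
        # separator chosen so it cannot extend either flanking match
        sep = "".join("A" if b != "A" else "C" for b in (ref[18], ref[17], ref[19], ref[20], ref[19]))
        read_seq = ref[:18] + sep + ref[20:40]
        hits = find_fragments_exact(rd(read_seq), index, min_fragment_len=16)
        got = {(h.ref_name, h.read_span, h.ref_span) for h in hits}
        assert got == brute_force_fragments(read_seq, {"a": ref}, 16)
        assert len(hits) == 2

    def test_n_never_matches(self):
        refs = seq_set("target", a="ACGUACGUACGUACGUACGU")
        index = build_index(refs, k=8)
        read = rd("ACGUACGUNCGUACGUACGU")
        hits = find_fragments_exact(read, index, min_fragment_len=16)
        assert hits == []

    @pytest.mark.parametrize("trial_seed", range(20))
    def test_agrees_with_all_substrings_oracle(self, trial_seed):
        rng = random.Random(trial_seed)
        refs = {
            f"ref{i}": random_rna(rng, rng.randint(10, 40))
            for i in range(rng.randint(1, 10))
        }
        read_seq = random_rna(rng, rng.randint(10, 60))
        if rng.random() < 0.7:  # plant a shared fragment so matches exist
            donor = rng.choice(list(refs))
            frag_len = rng.randint(8, min(20, len(refs[donor])))
            start = rng.randint(0, len(refs[donor]) - frag_len)
            pos = rng.randint(0, len(read_seq) - 1)
            read_seq = read_seq[:pos] + refs[donor][start : start + frag_len] + read_seq[pos:]
        index = build_index(seq_set("target", **refs), k=8)
        hits = find_fragments_exact(rd(read_seq), index, min_fragment_len=8)
        got = {(h.ref_name, h.read_span, h.ref_span) for h in hits}
        assert got == brute_force_fragments(read_seq, refs, 8)


class TestFindFragmentsAligned:
    def make(self, rng_seed=11):
        rng = random.Random(rng_seed)
        ref = random_rna(rng, 21)
        refs = seq_set("regulatory", m=ref)
        return ref, build_index(refs, k=8)

    def test_single_substitution_tolerated(self):
        ref, index = self.make()
        mutated = ref[:10] + ("A" if ref[10] != "A" else "C") + ref[11:]
        (hit,) = find_fragments_aligned(rd(mutated), index, SearchParams())
        assert hit.n_mismatch == 1
        assert hit.n_indel == 0

    def test_single_deletion_tolerated(self):
        ref, index = self.make()
        deleted = ref[:10] + ref[11:]
        (hit,) = find_fragments_aligned(rd(deleted), index, SearchParams())
        assert hit.n_indel == 1

    def test_perfect_copy_scores_length_times_match(self):
        ref, index = self.make()
        params = SearchParams()
        (hit,) = find_fragments_aligned(rd(ref), index, params)
        assert hit.align_score == len(ref) * params.align_match
        assert hit.read_span == (0, len(ref))

    def test_hit_cap_applies(self):
        rng = random.Random(3)
        core = random_rna(rng, 25)
        refs = {f"t{i}": random_rna(rng, 10) + core + random_rna(rng, 10) for i in range(6)}
        index = build_index(seq_set("target", **refs), k=8)
        params = SearchParams(max_hits_per_fragment=3)
        hits = find_fragments_aligned(rd(core), index, params)
        assert len(hits) == 3


def make_hit(role, name, read_span, score=None):
    from clashkit.chimera_search import FragmentHit

    length = read_span[1] - read_span[0]
    return FragmentHit(
        ref_name=name, ref_role=role, read_span=read_span,
        ref_span=(0, length), align_score=score if score is not None else float(length),
    )


class TestPairFragments:
    def pair(self, reg_span, tgt_span, **params):
        read = rd("A" * 60)
        return pair_fragments(
            read,
            [make_hit("regulatory", "r1", reg_span)],
            [make_hit("target", "t1", tgt_span)],
            SearchParams(**params),
        )

    def test_adjacent_fragments_pair_cleanly(self):
        (cand,) = self.pair((0, 21), (21, 46))
        assert (cand.overlap_nt, cand.gap_nt, cand.orientation) == (0, 0, "reg_first")
        assert cand.combined_score == 21 + 25

    def test_overlap_within_budget_accepted(self):
        (cand,) = self.pair((0, 21), (18, 40))
        assert cand.overlap_nt == 3
        assert cand.combined_score == 21 + 22 - 3

    def test_overlap_beyond_budget_rejected(self):
        assert self.pair((0, 21), (15, 40)) == []

    def test_gap_beyond_budget_rejected(self):
        assert self.pair((0, 21), (30, 50), max_gap_between=4) == []

    def test_target_first_orientation_detected(self):
        (cand,) = self.pair((25, 46), (0, 25))
        assert cand.orientation == "target_first"


class TestSearchStrict:
    def build(self):
        rng = random.Random(21)
        reg = random_rna(rng, 21)
        tgt = random_rna(rng, 120)
        regs = seq_set("regulatory", g1=reg)
        tgts = seq_set("target", t1=tgt)
        return reg, tgt, build_index(regs, 12), build_index(tgts, 12)

    def test_intact_guide_plus_exact_target_found(self):
        reg, tgt, ri, ti = self.build()
        read = rd(reg + tgt[40:65])
        (cand,) = search_strict(read, ri, ti, SearchParams(mode="strict"))
        assert cand.reg_hit.ref_span == (0, 21)
        assert cand.tgt_hit.ref_span == (40, 65)
        assert cand.orientation == "reg_first"
        assert cand.overlap_nt == cand.gap_nt == 0

    def test_guide_with_mismatch_rejected(self):
        reg, tgt, ri, ti = self.build()
        mutated = reg[:10] + ("A" if reg[10] != "A" else "C") + reg[11:]
        read = rd(mutated + tgt[40:65])
        assert search_strict(read, ri, ti, SearchParams(mode="strict")) == []

    def test_insertion_between_fragments_rejected(self):
        reg, tgt, ri, ti = self.build()
        read = rd(reg + "ACGU" + tgt[40:65])
        assert search_strict(read, ri, ti, SearchParams(mode="strict")) == []

    def test_target_first_order_searched(self):
        reg, tgt, ri, ti = self.build()
        read = rd(tgt[40:65] + reg)
        (cand,) = search_strict(read, ri, ti, SearchParams(mode="strict"))
        assert cand.orientation == "target_first"


class TestSearchScoredAndExhaustive:
    def build(self, seed=33):
        rng = random.Random(seed)
        reg = random_rna(rng, 21)
        t_long = random_rna(rng, 120)
        t_short = random_rna(rng, 120)
        regs = seq_set("regulatory", g1=reg)
        tgts = seq_set("target", tA=t_long, tB=t_short)
        return reg, tgts, build_index(regs, 8), build_index(tgts, 8)

    def test_scored_prefers_longer_target_interpretation(self):
        reg, tgts, ri, ti = self.build()
        read = rd(reg + tgts["tA"][30:55])  # 25 nt of tA
        out = search_scored(read, ri, ti, SearchParams(mode="scored"))
        assert len(out) == 1
        assert out[0].tgt_hit.ref_name == "tA"

    def test_scored_tie_breaks_to_lexicographic_target(self):
        rng = random.Random(9)
        reg = random_rna(rng, 21)
        frag = random_rna(rng, 25)
        tgts = seq_set(
            "target",
            tB=random_rna(rng, 40) + frag + random_rna(rng, 40),
            tA=random_rna(rng, 40) + frag + random_rna(rng, 40),
        )
        ri = build_index(seq_set("regulatory", g1=reg), 8)
        ti = build_index(tgts, 8)
        (cand,) = search_scored(rd(reg + frag), ri, ti, SearchParams(mode="scored"))
        assert cand.tgt_hit.ref_name == "tA"

    def test_exhaustive_reports_all_equal_matches(self):
        rng = random.Random(9)
        reg = random_rna(rng, 21)
        frag = random_rna(rng, 25)
        tgts = seq_set(
            "target",
            tA=random_rna(rng, 40) + frag + random_rna(rng, 40),
            tB=random_rna(rng, 40) + frag + random_rna(rng, 40),
        )
        ri = build_index(seq_set("regulatory", g1=reg), 8)
        ti = build_index(tgts, 8)
        cands = search_exhaustive(rd(reg + frag), ri, ti, SearchParams(mode="exhaustive"))
        assert {c.tgt_hit.ref_name for c in cands} == {"tA", "tB"}

    def test_no_match_read_yields_nothing(self):
        reg, tgts, ri, ti = self.build()
        read = rd("ACGU" * 10)
        assert search_scored(read, ri, ti, SearchParams(mode="scored")) == []
        assert search_exhaustive(read, ri, ti, SearchParams(mode="exhaustive")) == []


def candidate_key(cand):
    return (
        cand.read_id,
        cand.reg_hit.ref_name, cand.reg_hit.read_span, cand.reg_hit.ref_span,
        cand.tgt_hit.ref_name, cand.tgt_hit.read_span, cand.tgt_hit.ref_span,
        cand.orientation,
    )


class TestStringencyContainment:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_strict_subset_of_exhaustive_and_scored_element_of_it(self, seed):
        cfg, refs, reads, _ = make_library(seed=seed, decoy_multimap=True)
        strict, *_ = run_search(cfg, refs, reads, "strict")
        scored, *_ = run_search(cfg, refs, reads, "scored")
        exhaustive, *_ = run_search(cfg, refs, reads, "exhaustive")
        ex_keys = {candidate_key(c) for c in exhaustive}
        for cand in strict:
            assert candidate_key(cand) in ex_keys
        for cand in scored:
            assert candidate_key(cand) in ex_keys

    def test_exhaustive_recall_at_least_strict_on_multimap_library(self):
        from clashkit.synth import evaluate_recovery

        cfg, refs, reads, manifest = make_library(seed=4, decoy_multimap=True)
        strict, _, _, members = run_search(cfg, refs, reads, "strict")
        exhaustive, _, _, members_e = run_search(cfg, refs, reads, "exhaustive")
        rec_s = evaluate_recovery(strict, manifest, members)
        rec_e = evaluate_recovery(exhaustive, manifest, members_e)
        assert rec_e.recall >= rec_s.recall


class TestDeterminism:
    def test_identical_inputs_give_identical_candidates(self):
        cfg, refs, reads, _ = make_library(seed=5)
        first, *_ = run_search(cfg, refs, reads, "exhaustive")
        second, *_ = run_search(cfg, refs, reads, "exhaustive")
        assert [repr(c) for c in first] == [repr(c) for c in second]
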