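"""Multi-reference calling, QC scoring and library profiling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import partchar as pc
from partchar.parts import PartCombination, random_dna, revcomp
from partchar.tags import DemuxBin, Tag, TagPair
from partchar.genotyping import ReadCall, genotype_sample


def _bin(n_reads, colony_index=0):
    pair = TagPair(Tag("F1", "ACGTACG", "forward"),
                   Tag("R1", "TTGCATG", "reverse"), colony_index)
    return DemuxBin(pair=pair, read_ids=[f"r{i}" for i in range(n_reads)])


def _call(read_id, combo, passed=True):
    return ReadCall(read_id=read_id, best_construct=combo, best_score=100.0,
                    edit_distance=0, strand="+", query_coverage=1.0 if passed else 0.5,
                    passed=passed)


class TestReferences:
    def test_cartesian_product_of_slots(self, part_library, refs):
        assert len(refs.constructs) == 4 * 5 * 1 * 1
        combo = part_library.combinations()[0]
        inner = part_library.assemble(combo)
        assert refs.constructs[combo] == refs.flank5 + inner + refs.flank3

    def test_single_part_slots_give_one_construct(self):
        lib = pc.random_part_library(1, 1, seed=0)
        assert len(pc.build_references(lib).constructs) == 1

    def test_empty_slot_rejected(self):
        lib = pc.random_part_library(2, 2, seed=0)
        lib.slots["rbs"] = {}
        with pytest.raises(ValueError, match="rbs"):
            pc.build_references(lib)

    def test_duplicate_part_ids_rejected(self, tmp_path):
        fasta = tmp_path / "promoter.fasta"
        fasta.write_text(">P1\nACGTACGT\n>P1\nTTTTACGT\n")
        with pytest.raises(ValueError, match="duplicate"):
            pc.PartLibrary.from_fasta({"promoter": fasta})


class TestCallRead:
    def test_exact_read_identifies_its_construct(self, part_library, refs):
        caller = pc.ConstructCaller(refs)
        for combo in part_library.combinations()[:5]:
            call = caller.call("r", refs.constructs[combo])
            assert call.best_construct == combo
            assert call.query_coverage == pytest.approx(1.0)
            assert call.passed and not call.ambiguous

    def test_reverse_strand_read_called_identically(self, part_library, refs):
        caller = pc.ConstructCaller(refs)
        combo = part_library.combinations()[3]
        call = caller.call("r", revcomp(refs.constructs[combo]))
        assert call.best_construct == combo and call.passed
        assert call.strand == "-"

    def test_truncated_read_coverage_is_read_relative(self, part_library, refs):
        combo = part_library.combinations()[0]
        seq = refs.constructs[combo]
        call = pc.ConstructCaller(refs).call("r", seq[:int(0.9 * len(seq))])
        assert call.best_construct == combo
        assert call.query_coverage > 0.99
        assert call.passed

    def test_random_read_fails_coverage(self, refs):
        rng = np.random.default_rng(1)
        call = pc.ConstructCaller(refs).call("r", random_dna(250, rng))
        assert call.query_coverage < 0.95
        assert not call.passed

    def test_noisy_reads_still_recover_construct(self, part_library, refs):
        from partchar.simulate import mutate_sequence
        rng = np.random.default_rng(2)
        caller = pc.ConstructCaller(refs)
        combos = part_library.combinations()
        for i in range(20):
            combo = combos[i % len(combos)]
            noisy = mutate_sequence(refs.constructs[combo], rng, 0.05, 0.015, 0.015)
            call = caller.call(f"r{i}", noisy)
            assert call.best_construct == combo
            assert call.passed

    def test_circular_mode_handles_rotated_reads(self, part_library):
        refs = pc.build_references(part_library)
        combo = part_library.combinations()[2]
        seq = refs.constructs[combo]
        rotated = seq[100:] + seq[:100]
        call = pc.ConstructCaller(refs, circular=True).call("r", rotated)
        assert call.best_construct == combo and call.passed

    def test_empty_read_rejected(self, refs):
        with pytest.raises(ValueError, match="empty"):
            pc.ConstructCaller(refs).call("r", "")


class TestGenotypeSample:
    def test_pure_bin_scores_one(self):
        combo = PartCombination("P1", "R1", "T1")
        calls = [_call(f"r{i}", combo) for i in range(30)]
        g = genotype_sample(_bin(30), calls)
        assert (g.primary_count, g.second_count) == (30, 0)
        assert g.score1 == 1.0 and g.score2 == 1.0 and g.qc_pass

    def test_mixed_bin_arithmetic(self):
        a, b = PartCombination("P1", "R1", "T1"), PartCombination("P2", "R1", "T1")
        calls = ([_call(f"a{i}", a) for i in range(24)]
                 + [_call(f"b{i}", b) for i in range(6)])
        g = genotype_sample(_bin(40), calls)
        assert g.total_reads == 40
        assert g.score1 == pytest.approx(0.6)
        assert g.score2 == pytest.approx(0.75)
        assert g.qc_pass and g.genotype == a

    def test_low_depth_fails_qc_regardless_of_purity(self):
        combo = PartCombination("P1", "R1", "T1")
        calls = [_call(f"r{i}", combo) for i in range(10)]
        g = genotype_sample(_bin(10), calls)
        assert g.score1 == 1.0 and g.score2 == 1.0
        assert not g.qc_pass

    def test_threshold_is_strictly_greater(self):
        combo = PartCombination("P1", "R1", "T1")
        g = genotype_sample(_bin(15), [_call(f"r{i}", combo) for i in range(15)])
        assert not g.qc_pass  # total must exceed 15, not reach it
        g = genotype_sample(_bin(16), [_call(f"r{i}", combo) for i in range(16)])
        assert g.qc_pass

    def test_empty_bin_has_undefined_genotype(self):
        g = genotype_sample(_bin(20), [_call(f"r{i}", PartCombination("P1", "R1", "T1"),
                                             passed=False) for i in range(20)])
        assert g.genotype is None and not g.qc_pass and g.score1 == 0.0

    def test_coverage_failed_reads_dilute_score1(self):
        combo = PartCombination("P1", "R1", "T1")
        calls = ([_call(f"r{i}", combo) for i in range(10)]
                 + [_call(f"f{i}", combo, passed=False) for i in range(30)])
        g = genotype_sample(_bin(40), calls)
        assert g.score1 == pytest.approx(0.25)
        assert not g.qc_pass
        g2 = genotype_sample(_bin(40), calls, count_failed_in_total=False)
        assert g2.score1 == 1.0

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(primary=st.integers(1, 50), second=st.integers(0, 50),
           failed=st.integers(0, 20))
    def test_scores_bounded_and_monotone(self, primary, second, failed):
        second = min(second, primary)  # runner-up cannot beat the mode
        a, b = PartCombination("P1", "R1", "T1"), PartCombination("P2", "R1", "T1")
        calls = ([_call(f"a{i}", a) for i in range(primary)]
                 + [_call(f"b{i}", b) for i in range(second)]
                 + [_call(f"f{i}", a, passed=False) for i in range(failed)])
        total = primary + second + failed
        g = genotype_sample(_bin(total), calls)
        assert 0.0 <= g.score1 <= 1.0
        assert 0.0 <= g.score2 <= 1.0
        if second > 0:
            fewer = genotype_sample(
                _bin(total),
                [c for c in calls if not c.read_id.startswith("b")]
                + [_call(f"b{i}", b) for i in range(second - 1)])
            assert fewer.score2 >= g.score2


class TestLibraryProfile:
    def test_single_combination_ratio_one(self):
        combo = PartCombination("P1", "R1", "T1")
        profile = pc.profile_library([_call(f"r{i}", combo) for i in range(50)])
        assert profile.combination_ratios[combo] == 1.0
        assert profile.slot_marginals["promoter"]["P1"] == 1.0

    def test_marginals_consistent_with_counts(self):
        a, b = PartCombination("P1", "R1", "T1"), PartCombination("P2", "R2", "T1")
        calls = [_call(f"a{i}", a) for i in range(30)] + \
                [_call(f"b{i}", b) for i in range(10)]
        profile = pc.profile_library(calls)
        assert sum(profile.combination_ratios.values()) == pytest.approx(1.0)
        assert profile.slot_marginals["promoter"]["P1"] == pytest.approx(0.75)
        assert profile.slot_marginals["rbs"]["R2"] == pytest.approx(0.25)

    def test_no_passed_calls_rejected(self):
        combo = PartCombination("P1", "R1", "T1")
        with pytest.raises(ValueError, match="no coverage-passing"):
            pc.profile_library([_call("r", combo, passed=False)])

    def test_input_ratio_comparison_spearman(self):
        rng = np.random.default_rng(3)
        proms = {f"P{i}": float(r) for i, r in
                 enumerate(rng.dirichlet([2] * 4), start=1)}
        rbss = {f"R{i}": float(r) for i, r in
                enumerate(rng.dirichlet([2] * 5), start=1)}
        ratios = {"promoter": proms, "rbs": rbss, "terminator": {"T1": 1.0}}
        combos = pc.simulate_assembly(ratios, 20000, seed=4)
        calls = [_call(f"r{i}", c) for i, c in enumerate(combos)]
        profile = pc.profile_library(calls, input_ratios=ratios)
        assert profile.spearman_rho > 0.9
        assert len(profile.comparison) == 20


class TestEndToEndGenotyping:
    def test_96_colony_recovery(self, noisy_pool, pairs96, refs, colony_specs):
        """Full demux → call → QC chain on the nominal noisy pool: QC-passing
        bins overwhelmingly agree with the programmed genotypes."""
        truth = {i: combo for i, combo, _ in colony_specs}
        bins, _ = pc.demultiplex(noisy_pool, pairs96, max_edit=1)
        caller = pc.ConstructCaller(refs)
        n_pass = n_correct = 0
        for b in bins:
            if not b.n_reads:
                continue
            calls = [caller.call(a.read_id, a.trimmed_seq) for a in b.assignments]
            g = pc.genotype_sample(b, calls)
            if g.qc_pass:
                n_pass += 1
                n_correct += g.genotype == truth[g.colony_index]
        assert n_pass >= 90
        assert n_correct / n_pass >= 0.95

    def test_pure_bins_always_pass_qc_with_true_genotype(self, pairs96, refs,
                                                         colony_specs):
        """Purity-1 fixture (error-free, deep bins): every bin passes QC and
        no QC-passing bin carries a wrong genotype."""
        specs = colony_specs[:20]
        truth = {i: combo for i, combo, _ in specs}
        pool = pc.simulate_tagged_reads(
            specs, refs, pc.ReadSimConfig(substitution_rate=0, insertion_rate=0,
                                          deletion_rate=0, reads_per_colony=18,
                                          seed=13))
        bins, _ = pc.demultiplex(pool, pairs96, max_edit=1)
        caller = pc.ConstructCaller(refs)
        n_pass = 0
        for b in bins:
            if not b.n_reads:
                continue
            calls = [caller.call(a.read_id, a.trimmed_seq) for a in b.assignments]
            g = pc.genotype_sample(b, calls)
            assert g.qc_pass
            assert g.genotype == truth[g.colony_index]
            n_pass += 1
        assert n_pass == 20
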