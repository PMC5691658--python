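"""Pileup I/O, polymorphism calling, coding effects, and the frequency spectrum."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from obgenome.genome import CircularGenome
from obgenome.orfs import EvidenceRecord, find_orfs, resolve_overlaps
from obgenome.variants import (PileupColumn, Polymorphism, call_polymorphisms,
                               classify_all, classify_effect, read_pileup,
                               summarize_frequencies, write_pileup)


def _col(position=1, ref="A", depth=200, **alts):
    counts = {ref: depth - sum(alts.values())}
    counts.update(alts)
    return PileupColumn(position, ref, depth, counts)


class TestPileupIO:
    def test_empty_file(self, tmp_path):
        p = tmp_path / "x.tsv"
        p.write_text("")
        assert read_pileup(p) == []

    def test_one_row(self, tmp_path):
        p = tmp_path / "x.tsv"
        write_pileup([_col(depth=100, C=5)], p)
        (col,) = read_pileup(p)
        assert col.depth == 100 and col.base_counts == {"A": 95, "C": 5}

    def test_counts_exceeding_depth_error_names_position(self, tmp_path):
        p = tmp_path / "x.tsv"
        p.write_text("position\tref\tdepth\tA\tC\tG\tT\tins\tdel\n"
                     "7\tA\t10\t9\t9\t0\t0\t.\t.\n")
        with pytest.raises(ValueError, match="position 7"):
            read_pileup(p)

    def test_simulated_pileup_round_trips(self, tmp_path, small_fixture):
        from obgenome.simulate import simulate_pileup

        cfg, genome, truth = small_fixture
        cols = simulate_pileup(genome, truth, depth=60, seed=3)
        p = tmp_path / "pileup.tsv"
        write_pileup(cols, p)
        back = read_pileup(p)
        assert len(back) == len(cols)
        for a, b in zip(cols, back):
            assert (a.position, a.ref_base, a.depth) == (b.position, b.ref_base, b.depth)
            assert a.base_counts == b.base_counts
            assert a.ins_counts == b.ins_counts and a.del_counts == b.del_counts


class TestCallPolymorphisms:
    def test_all_reference_column_yields_no_call(self):
        assert call_polymorphisms([_col(depth=200)]) == []

    def test_frequency_arithmetic(self):
        (call,) = call_polymorphisms([_col(depth=200, G=25)])
        assert call.frequency == 12.5 and call.alt == "G" and call.kind == "SNP"

    def test_depth_floor(self):
        assert call_polymorphisms([_col(depth=19, G=5)], min_depth=20) == []

    def test_multiallelic_column_gives_one_call_per_allele(self):
        calls = call_polymorphisms([_col(depth=300, C=30, G=45)])
        assert [(c.alt, c.frequency) for c in calls] == [("C", 10.0), ("G", 15.0)]

    def test_indels_share_the_depth_denominator(self):
        col = PileupColumn(5, "A", 200, {"A": 170}, {"CTG": 18}, {2: 12})
        calls = call_polymorphisms([col])
        by_kind = {c.kind: c for c in calls}
        assert by_kind["insertion"].frequency == 9.0
        assert by_kind["deletion"].frequency == 6.0 and by_kind["deletion"].alt == "2"

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 500), st.integers(0, 500), st.integers(2, 50),
           st.floats(0.5, 20.0))
    def test_filter_soundness(self, ref_n, alt_n, min_alt, min_freq):
        depth = ref_n + alt_n
        cols = [PileupColumn(1, "A", depth, {"A": ref_n, "G": alt_n})] if depth else []
        calls = call_polymorphisms(cols, min_depth=20, min_alt=min_alt,
                                   min_freq=min_freq)
        for c in calls:
            assert c.depth >= 20 and c.alt_count >= min_alt and c.frequency >= min_freq

    def test_row_order_irrelevant_after_sorting(self):
        cols = [_col(position=9, depth=100, G=10), _col(position=2, depth=100, C=10)]
        a = call_polymorphisms(cols)
        b = call_polymorphisms(cols[::-1])
        assert [(c.position, c.alt) for c in a] == [(c.position, c.alt) for c in b]


def _annotated_genome(cds: str, strand: str = "+"):
    """A linear genome holding one accepted ORF built from ``cds``."""
    from obgenome.genome import reverse_complement

    pad_l, pad_r = "CCTTCC" * 10, "TTCCTT" * 10
    insert = cds if strand == "+" else reverse_complement(cds)
    g = CircularGenome("t", pad_l + insert + pad_r, topology="linear")
    cands = find_orfs(g, min_codons=len(cds) // 3 - 1)
    ev = [EvidenceRecord(c.orf_id, True, "subj") for c in cands]
    anns = resolve_overlaps(cands, ev, g.length, min_codons=len(cds) // 3 - 1)
    assert any(a.accepted for a in anns)
    return g, anns


def _snp(position, ref, alt, kind="SNP"):
    return Polymorphism(position, ref, alt, kind, 20, 200, 10.0)


class TestClassifyEffect:
    def test_third_position_wobble_is_synonymous(self):
        g, anns = _annotated_genome("ATG" + "GCA" * 60 + "TAA")
        pos = 60 + 3 + 3  # third base of the first GCA codon (GCA->GCG, Ala->Ala)
        (out,) = classify_effect(_snp(pos, "A", "G"), anns, g)
        assert out.effect == "synonymous" and out.orf_id

    def test_second_position_change_is_nonsynonymous(self):
        g, anns = _annotated_genome("ATG" + "GCA" * 60 + "TAA")
        pos = 60 + 3 + 2  # GCA -> GAA, Ala -> Glu
        (out,) = classify_effect(_snp(pos, "C", "A"), anns, g)
        assert out.effect == "nonsynonymous"

    def test_stop_gain_is_nonsense(self):
        g, anns = _annotated_genome("ATG" + "TCA" * 60 + "TAA")
        pos = 60 + 3 + 2  # TCA -> TAA
        (out,) = classify_effect(_snp(pos, "C", "A"), anns, g)
        assert out.effect == "nonsense"

    def test_minus_strand_codon_arithmetic(self):
        g, anns = _annotated_genome("ATG" + "GCA" * 60 + "TAA", strand="-")
        # transcript offset 5 = third base of first GCA; genomic base is complement
        accepted = next(a for a in anns if a.accepted)
        assert accepted.candidate.strand == "-"
        pos = accepted.candidate.start - 5  # walking downstream on minus strand
        ref = g.sequence[pos - 1]
        assert ref == "T"  # complement of transcript A
        (out,) = classify_effect(_snp(pos, ref, "C"), anns, g)  # transcript A->G
        assert out.effect == "synonymous"

    def test_intergenic_call(self):
        g, anns = _annotated_genome("ATG" + "GCA" * 60 + "TAA")
        (out,) = classify_effect(_snp(3, "T", "A"), anns, g)
        assert out.effect == "intergenic" and out.orf_id == ""

    def test_frameshift_vs_inframe_indel(self):
        g, anns = _annotated_genome("ATG" + "GCA" * 60 + "TAA")
        (fs,) = classify_effect(_snp(70, "G", "4", kind="deletion"), anns, g)
        assert fs.effect == "frameshift"
        (inframe,) = classify_effect(_snp(70, "G", "3", kind="deletion"), anns, g)
        assert inframe.effect == "nonsynonymous"

    def test_call_in_two_overlapping_orfs_reported_per_orf(self):
        # two accepted overlapping ORFs (both with homology evidence)
        cds_a = "ATG" + "GCA" * 60 + "TAA"
        g = CircularGenome("t", "CCTTCC" + cds_a + "CCTTCC", topology="linear")
        cands = find_orfs(g, min_codons=10)
        # synthesise a second candidate on the minus strand covering the same span
        from obgenome.orfs import OrfCandidate

        other = OrfCandidate("opp", 150, 40, "-", 0, 35)
        cands = cands + [other]
        ev = [EvidenceRecord(c.orf_id, True, "subj") for c in cands]
        anns = resolve_overlaps(cands, ev, g.length, min_codons=10)
        out = classify_effect(_snp(80, g.sequence[79], "A"), anns, g)
        assert len(out) == 2 and {o.orf_id for o in out} == {"orf001", "opp"}

    def test_position_outside_genome_errors(self):
        g, anns = _annotated_genome("ATG" + "GCA" * 60 + "TAA")
        with pytest.raises(ValueError):
            classify_effect(_snp(10_000, "A", "C"), anns, g)

    def test_planted_effects_recovered(self, default_fixture):
        """End-to-end: intended coding effects of the planted high-frequency
        substitutions are reproduced by annotation + classification."""
        _, genome, truth = default_fixture
        cands = find_orfs(genome, min_codons=50)
        ev = [EvidenceRecord(c.orf_id, True, "planted")
              for c in cands]
        anns = resolve_overlaps(cands, ev, genome.length)
        named = [v for v in truth.variants if v.effect in ("synonymous", "nonsynonymous")
                 and v.kind == "SNP"]
        assert len(named) == 5
        for v in named:
            call = Polymorphism(v.position, v.ref, v.alt, "SNP", 100, 941,
                                v.frequency)
            effects = {o.effect for o in classify_effect(call, anns, genome)}
            assert v.effect in effects

    def test_same_orf_hosts_the_close_pair(self, default_fixture):
        _, genome, truth = default_fixture
        pair = [v for v in truth.variants
                if v.frequency in (11.08, 10.10)]
        assert len(pair) == 2
        assert pair[0].orf_index == pair[1].orf_index
        assert abs(pair[0].position - pair[1].position) == 11


class TestSummarizeFrequencies:
    def test_empty(self):
        s = summarize_frequencies([])
        assert s["total"] == 0 and s["ge"][8.0] == 0 and s["top"] == []

    def test_threshold_counts_and_top_list(self):
        freqs = [17.44, 14.63, 12.5, 11.08, 10.10, 5.0, 4.0]
        polys = [Polymorphism(i + 1, "A", "C", "SNP", 10, 100, f)
                 for i, f in enumerate(freqs)]
        s = summarize_frequencies(polys, thresholds=[6.0, 8.0], top_k=5)
        assert s["total"] == 7
        assert s["ge"][8.0] == 5 and s["le"][6.0] == 2
        assert [f for _, f in s["top"]] == [17.44, 14.63, 12.5, 11.08, 10.10]


class TestBinomialRecovery:
    def test_planted_frequency_within_three_se(self, default_fixture, default_pileup):
        """Estimated frequencies of the five reported-high variants sit within
        3 binomial standard errors of the planted values at 941x."""
        _, _, truth = default_fixture
        _, calls = default_pileup
        by_pos = {}
        for c in calls:
            by_pos.setdefault((c.position, c.kind), c)
        for f in (17.44, 14.63, 12.5, 11.08, 10.10):
            v = next(v for v in truth.variants if v.frequency == f)
            c = by_pos[(v.position, v.kind)]
            se = 100 * np.sqrt((f / 100) * (1 - f / 100) / 941)
            assert abs(c.frequency - f) <= 3 * se

    def test_mean_absolute_error_bounded_over_seeds(self, small_fixture):
        """MAE of recovered frequencies over several pileup seeds obeys the
        binomial sampling bound 3*sqrt(f(1-f)/d)."""
        from obgenome.simulate import simulate_pileup

        cfg, genome, truth = small_fixture
        target = [v for v in truth.variants if v.kind == "SNP"][:40]
        depth = 900
        errs = {v.position: [] for v in target}
        for seed in range(5):
            cols = simulate_pileup(genome, truth, depth=depth, seed=50 + seed)
            calls = {c.position: c for c in call_polymorphisms(cols)}
            for v in target:
                if v.position in calls:
                    errs[v.position].append(abs(calls[v.position].frequency - v.frequency))
        for v in target:
            assert errs[v.position], f"variant at {v.position} never recovered"
            f = v.frequency / 100
            bound = 3 * np.sqrt(f * (1 - f) / depth) * 100
            assert np.mean(errs[v.position]) <= bound
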