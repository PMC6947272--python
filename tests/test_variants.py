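"""Pileup, candidate calling, Fisher filtering and hotspot annotation."""

from math import comb

import pytest

from nanoamp.align import align_read
from nanoamp.panel import Amplicon, GenomicInterval, Panel, PrimerPair
from nanoamp.simulate import (
    ErrorProfile,
    SimSample,
    VariantSpec,
    apply_variants,
    simulate_reads,
    validation_cohort,
)
from nanoamp.variants import (
    FilterConfig,
    PileupColumn,
    VariantCall,
    VariantCallingError,
    annotate_hotspots,
    call_candidates,
    cohort_final_calls,
    cohort_hotspot_summary,
    default_hotspot_catalog,
    filter_somatic,
    fisher_test,
    pileup,
)

CFG = FilterConfig()


def fisher_oracle(ta, td, na, nd):
    """One-sided hypergeometric tail by direct enumeration."""
    N = td + nd
    K = ta + na
    denom = comb(N, td)
    p = 0.0
    for x in range(ta, min(td, K) + 1):
        if K - x > nd:
            continue
        p += comb(K, x) * comb(N - K, td - x) / denom
    return p


@pytest.fixture(scope="module")
def small_amp(panel):
    return panel["FLT3_ex20"]


def perfect_alignments(ref, n, name):
    return [align_read(ref, ref, read_id=f"r{i}", amplicon=name) for i in range(n)]


class TestPileup:
    def test_perfect_reads_count_reference_alleles(self, small_amp):
        ref = small_amp.reference_seq
        cols = pileup(perfect_alignments(ref, 10, small_amp.name), ref)
        for col in cols:
            assert col.depth == 10
            assert col.allele_counts == {ref[col.position - 1]: 10}

    def test_substituted_reads_split_the_column(self, small_amp):
        ref = small_amp.reference_seq
        alt = "A" if ref[6] != "A" else "C"
        mutant = ref[:6] + alt + ref[7:]
        alns = perfect_alignments(ref, 6, small_amp.name) + [
            align_read(mutant, ref, read_id=f"m{i}", amplicon=small_amp.name)
            for i in range(4)
        ]
        col = pileup(alns, ref)[6]
        assert col.allele_counts == {ref[6]: 6, alt: 4}
        assert col.depth == 10

    def test_deletion_recorded_at_first_deleted_position(self, small_amp):
        ref = small_amp.reference_seq
        v = VariantSpec(kind="DEL", amplicon=small_amp.name, position=50,
                        ref_allele=ref[49:52])
        mutant = apply_variants(ref, [v])
        alns = [align_read(mutant, ref, read_id="d", amplicon=small_amp.name)]
        cols = pileup(alns, ref)
        # left-normalization may shift within a repeat; the allele must be
        # recorded as a 3-bp deletion at the normalized position
        del_cols = [c for c in cols if any(k.startswith("del3") for k in c.allele_counts)]
        assert len(del_cols) == 1
        assert abs(del_cols[0].position - 50) <= 2

    def test_insertion_attached_to_preceding_position(self, small_amp):
        ref = small_amp.reference_seq
        # pick an anchor whose context does not allow left-shifting
        pos = 100
        v = VariantSpec(kind="INS", amplicon=small_amp.name, position=pos,
                        alt_allele="TTAAGG")
        mutant = apply_variants(ref, [v])
        alns = [align_read(mutant, ref, read_id="i", amplicon=small_amp.name)]
        cols = pileup(alns, ref)
        ins_cols = [c for c in cols
                    if any(k.startswith("ins") for k in c.allele_counts)]
        assert len(ins_cols) == 1
        assert abs(ins_cols[0].position - pos) <= 2

    def test_depth_conservation_for_spanning_reads(self, small_amp):
        ref = small_amp.reference_seq
        cols = pileup(perfect_alignments(ref, 5, small_amp.name), ref)
        for col in cols:
            assert sum(col.allele_counts.values()) == col.depth


class TestCallCandidates:
    def _column(self, amp_ref, pos, allele, count, depth):
        counts = {amp_ref[pos - 1]: depth - count, allele: count}
        return PileupColumn(amplicon="a", position=pos, depth=depth,
                            allele_counts=counts)

    def test_snv_threshold_boundary(self, small_amp):
        ref = small_amp.reference_seq
        alt = "A" if ref[9] != "A" else "C"
        below = self._column(ref, 10, alt, 99, 1000)
        at = self._column(ref, 10, alt, 100, 1000)
        assert call_candidates([below], ref, CFG) == []
        calls = call_candidates([at], ref, CFG)
        assert len(calls) == 1 and calls[0].kind == "SNV"

    def test_indel_threshold_is_higher(self, small_amp):
        ref = small_amp.reference_seq
        ins = self._column(ref, 10, "insTCTG", 120, 1000)  # 12% < 15%
        assert call_candidates([ins], ref, CFG) == []
        ins_ok = self._column(ref, 10, "insTCTG", 150, 1000)
        calls = call_candidates([ins_ok], ref, CFG)
        assert len(calls) == 1 and calls[0].kind == "INS" \
            and calls[0].alt_allele == "TCTG"

    def test_low_depth_flagged_not_dropped(self, small_amp):
        ref = small_amp.reference_seq
        alt = "A" if ref[9] != "A" else "C"
        col = self._column(ref, 10, alt, 15, 40)  # 37.5% VAF but depth 40
        calls = call_candidates([col], ref, CFG)
        assert len(calls) == 1
        assert calls[0].filters == {"low_depth"}

    def test_spiked_snv_vaf_recovered_under_noise(self, panel, profiles):
        amp = panel["IDH1_ex4"]
        ref = amp.reference_seq
        alt = "A" if ref[199] != "A" else "C"
        v = VariantSpec(kind="SNV", amplicon=amp.name, position=200,
                        ref_allele=ref[199], alt_allele=alt, vaf=0.30)
        s = SimSample("s", "", variants=(v,), depth_per_amplicon=600)
        res = simulate_reads(Panel([amp]), [s], profiles, seed=19)
        alns = [align_read(seq, ref, read_id=rid, amplicon=amp.name)
                for rid, seq in res.reads]
        calls = call_candidates(pileup(alns, ref), ref, CFG)
        hits = [c for c in calls if c.position == 200 and c.alt_allele == alt]
        assert len(hits) == 1
        # measured VAF sits below the spiked fraction: ~15% of carrier reads
        # lose the allele to an error at the locus or to realignment, the
        # same attenuation seen when nanopore VAFs are compared with a
        # second platform on real samples
        assert abs(hits[0].tumor_vaf - 0.30) <= 0.08


class TestFisher:
    def test_no_signal_is_one(self):
        assert fisher_test(0, 100, 0, 100) == pytest.approx(1.0)

    def test_matches_enumeration_example(self):
        assert fisher_test(10, 20, 0, 20) == pytest.approx(
            fisher_oracle(10, 20, 0, 20), rel=1e-9)

    def test_one_sidedness(self):
        assert fisher_test(2, 20, 10, 20) >= 0.5

    def test_zero_depth_rejected(self):
        with pytest.raises(VariantCallingError):
            fisher_test(0, 0, 0, 10)

    def test_exhaustive_small_margins(self):
        for td in range(1, 13):
            for nd in range(1, 13):
                for ta in range(td + 1):
                    for na in range(nd + 1):
                        assert fisher_test(ta, td, na, nd) == pytest.approx(
                            fisher_oracle(ta, td, na, nd), rel=1e-8, abs=1e-12)


class TestFilterSomatic:
    def _nc_pileup(self, amp_ref, pos, allele, count, depth):
        cols = []
        for p in range(1, len(amp_ref) + 1):
            counts = {amp_ref[p - 1]: depth}
            if p == pos and count:
                counts = {amp_ref[p - 1]: depth - count, allele: count}
            cols.append(PileupColumn("a", p, depth, counts))
        return cols

    def _candidate(self, ref, pos, alt, vaf, depth=500):
        return VariantCall(
            amplicon="a", position=pos, ref_allele=ref[pos - 1], alt_allele=alt,
            kind="SNV", tumor_vaf=vaf, tumor_alt=int(vaf * depth),
            tumor_depth=depth,
        )

    def test_clean_nc_passes_directly(self, small_amp):
        ref = small_amp.reference_seq
        alt = "A" if ref[19] != "A" else "C"
        cand = self._candidate(ref, 20, alt, 0.35)
        nc = self._nc_pileup(ref, 20, alt, 10, 500)  # 2% in NC
        out = filter_somatic([cand], nc, CFG)
        assert out[0].status == "PASS"
        assert out[0].nc_vaf == pytest.approx(0.02)

    def test_small_delta_fails(self, small_amp):
        ref = small_amp.reference_seq
        alt = "A" if ref[19] != "A" else "C"
        cand = self._candidate(ref, 20, alt, 0.25)
        nc = self._nc_pileup(ref, 20, alt, 100, 500)  # 20% in NC
        out = filter_somatic([cand], nc, CFG)
        assert out[0].status == "FAIL"
        assert "low_delta" in out[0].filters and "nc_shared" in out[0].filters

    def test_large_delta_with_significant_p_passes(self, small_amp):
        ref = small_amp.reference_seq
        alt = "A" if ref[19] != "A" else "C"
        cand = self._candidate(ref, 20, alt, 0.40, depth=500)
        nc = self._nc_pileup(ref, 20, alt, 60, 500)  # 12% in NC
        out = filter_somatic([cand], nc, CFG)
        assert out[0].status == "PASS"
        p = fisher_oracle(200, 500, 60, 500)
        assert out[0].fisher_p == pytest.approx(p, rel=1e-6)
        assert p <= 0.01

    def test_missing_nc_locus_is_an_error(self, small_amp):
        ref = small_amp.reference_seq
        alt = "A" if ref[19] != "A" else "C"
        cand = self._candidate(ref, 20, alt, 0.4)
        with pytest.raises(VariantCallingError, match="negative-control"):
            filter_somatic([cand], [], CFG)
        short_nc = self._nc_pileup(ref, 20, alt, 0, 500)[:10]  # truncated NC
        with pytest.raises(VariantCallingError):
            filter_somatic([cand], short_nc, CFG)

    def test_two_ncs_must_both_be_clean(self, small_amp):
        ref = small_amp.reference_seq
        alt = "A" if ref[19] != "A" else "C"
        cand = self._candidate(ref, 20, alt, 0.25)
        clean = self._nc_pileup(ref, 20, alt, 5, 500)
        dirty = self._nc_pileup(ref, 20, alt, 100, 500)
        out = filter_somatic([cand], [clean, dirty], CFG)
        assert out[0].status == "FAIL"


class TestHomopolymerArtifact:
    def test_recurrent_artifact_never_passes(self, profiles):
        """A deletion artifact at equal VAF in tumor and NC is filtered."""
        rng_ref = (
            "ACGTGACTGTCCTGATCGGCTA" + "A" * 12 + "CGATCGTAGCTAGCATGCTAGCTAGG"
        ) * 4
        amp = Amplicon(
            name="hp", gene="HP",
            interval=GenomicInterval("chr1", 1000, 1000 + len(rng_ref)),
            primers=PrimerPair("ACGTACGTAC", "TGCATGCATG"),
            reference_seq=rng_ref,
        )
        sub = Panel([amp])
        profile = ErrorProfile(2.5, 9.0, 3.5, homopolymer_del_boost=1.0)
        tumor = SimSample("t", "", depth_per_amplicon=250)
        nc = SimSample("n", "", depth_per_amplicon=250)
        res_t = simulate_reads(sub, [tumor], {"hp": profile}, seed=41)
        res_n = simulate_reads(sub, [nc], {"hp": profile}, seed=42)
        alns_t = [align_read(s, rng_ref, read_id=r, amplicon="hp")
                  for r, s in res_t.reads]
        alns_n = [align_read(s, rng_ref, read_id=r, amplicon="hp")
                  for r, s in res_n.reads]
        cands = call_candidates(pileup(alns_t, rng_ref), rng_ref, CFG)
        out = filter_somatic(cands, pileup(alns_n, rng_ref), CFG)
        assert all(c.status == "FAIL" for c in out if c.kind == "DEL")


class TestHotspots:
    def test_flt3_d835_locus(self):
        call = VariantCall("", 0, "C", "A", "SNV", 0.5,
                           chrom="chr13", genomic_pos=28592642)
        annotate_hotspots([call])
        assert call.hotspot == "FLT3 p.D835"

    def test_npm1_frameshift_insertion_rule(self):
        call = VariantCall("", 0, "", "TCTG", "INS", 0.3,
                           chrom="chr5", genomic_pos=170837547)
        annotate_hotspots([call])
        assert call.hotspot == "NPM1 p.W288fs"

    def test_inframe_insertion_not_labelled(self):
        call = VariantCall("", 0, "", "TCT", "INS", 0.3,
                           chrom="chr5", genomic_pos=170837547)
        annotate_hotspots([call])
        assert call.hotspot is None

    def test_uncatalogued_locus_unlabelled(self):
        call = VariantCall("", 0, "G", "A", "SNV", 0.5,
                           chrom="chr1", genomic_pos=12345)
        annotate_hotspots([call])
        assert call.hotspot is None

    def test_amplicon_coordinates_lifted_via_panel(self, panel):
        amp = panel["FLT3_ex20"]
        pos = amp.from_genomic(28592642)
        call = VariantCall(amp.name, pos, "C", "A", "SNV", 0.5)
        annotate_hotspots([call], panel=panel)
        assert call.hotspot == "FLT3 p.D835"


class TestCohortSummary:
    def test_empty_cohort(self):
        assert cohort_hotspot_summary({})["total"] == 0

    def test_single_npm1_case(self):
        call = VariantCall("", 0, "", "TCTG", "INS", 0.3,
                           chrom="chr5", genomic_pos=170837547)
        annotate_hotspots([call])
        summary = cohort_hotspot_summary({"case1": [call]})
        assert summary["NPM1 p.W288fs"] == 1 and summary["total"] == 1

    def test_validated_cohort_counts(self):
        calls = cohort_final_calls(validation_cohort())
        for case_calls in calls.values():
            annotate_hotspots(case_calls)
        summary = cohort_hotspot_summary(calls)
        assert summary == {
            "NPM1 p.W288fs": 7, "FLT3 p.D835": 1, "IDH1 p.R132": 2,
            "IDH2 p.R140": 4, "IDH2 p.R172": 0, "total": 14,
        }
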