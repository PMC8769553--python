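"""Artifact filters: thresholds at their boundaries, per-category policy,
planted-artifact precision/recall, and intron-retention class codes."""

import numpy as np
import pytest

from lrsplice.classify import StructuralCall, StructuralCategory, classify_catalog
from lrsplice.core import Genome, PeakIndex, SpliceJunction, build_reference_index
from lrsplice.qc import (
    QcConfig,
    QcFlags,
    apply_filter_policy,
    canonical_status,
    compute_qc_flags,
    detect_intrapriming,
    detect_intron_retention,
    detect_rt_switch,
    junction_support_filter,
    support_rate_report,
    validate_ends,
    EndSupport,
)
from conftest import tx


def _genome(seq):
    return Genome({"chr1": seq})


class TestIntrapriming:
    def _setup(self, downstream, tts_at_end=False):
        # '+' transcript ending at 200; reference TTS far away unless tts_at_end
        seq = "C" * 200 + downstream + "C" * 600
        g = _genome(seq)
        t = tx("q", "", [(50, 200)])
        ref_end = 200 if tts_at_end else 500
        ref = build_reference_index([tx("r1", "g1", [(40, ref_end)])])
        return t, g, ref

    def test_end_at_annotated_tts_is_reliable(self):
        t, g, ref = self._setup("A" * 20, tts_at_end=True)
        far, a_rich, no_db = detect_intrapriming(t, g, PeakIndex(), ref)
        assert not far and a_rich and no_db

    def test_all_three_flags_give_unreliable(self):
        t, g, ref = self._setup("A" * 20)
        far, a_rich, no_db = detect_intrapriming(t, g, PeakIndex(), ref)
        assert far and a_rich and no_db

    def test_exactly_80_percent_a_is_reliable(self):
        t, g, ref = self._setup("A" * 16 + "C" * 4)  # exactly 0.80, strict >
        _, a_rich, _ = detect_intrapriming(t, g, PeakIndex(), ref)
        assert not a_rich

    def test_polya_db_overlap_rescues(self):
        t, g, ref = self._setup("A" * 20)
        db = PeakIndex()
        db.add("chr1", 195, 205)
        _, _, no_db = detect_intrapriming(t, g, db, ref)
        assert not no_db

    def test_minus_strand_reads_sense_adenines(self):
        # 3' end of a '-' transcript is its genomic start; downstream is
        # leftward, and sense A is genomic T
        seq = "C" * 180 + "T" * 20 + "G" * 400
        g = _genome(seq)
        t = tx("q", "", [(200, 350)], "-")
        ref = build_reference_index([tx("r1", "g1", [(500, 700)], "-")])
        far, a_rich, no_db = detect_intrapriming(t, g, PeakIndex(), ref)
        assert a_rich and far and no_db


class TestJunctionSupport:
    t = tx("q", "", [(0, 100), (200, 300), (400, 500)])

    def test_all_junctions_at_five_reads_pass(self):
        cov = {(100, 200): 5, (300, 400): 5}
        assert junction_support_filter(self.t, cov, lr_sample_count=1)

    def test_three_lr_samples_rescue_low_coverage(self):
        cov = {(100, 200): 4, (300, 400): 50}
        assert junction_support_filter(self.t, cov, lr_sample_count=3)

    def test_missing_junction_counts_as_zero(self):
        assert not junction_support_filter(self.t, {(100, 200): 9}, lr_sample_count=2)


class TestCanonical:
    def test_gt_ag_plus(self):
        g = _genome("C" * 100 + "GT" + "C" * 50 + "AG" + "C" * 100)
        j = SpliceJunction("chr1", 100, 154, "+")
        assert canonical_status(j, g) == "canonical"

    def test_ct_ac_minus_is_canonical(self):
        g = _genome("C" * 100 + "CT" + "G" * 50 + "AC" + "C" * 100)
        j = SpliceJunction("chr1", 100, 154, "-")
        assert canonical_status(j, g) == "canonical"

    @pytest.mark.parametrize("pair", [("GT", "TG"), ("CA", "AG"), ("GC", "AC")])
    def test_noncanonical_pairs(self, pair):
        g = _genome("C" * 100 + pair[0] + "C" * 50 + pair[1] + "C" * 100)
        j = SpliceJunction("chr1", 100, 154, "+")
        assert canonical_status(j, g) == "noncanonical"


class TestRtSwitch:
    def test_planted_repeat_detected(self):
        rep = "ACGTACGT"
        seq = "C" * 92 + rep + "GT" + "T" * 50 + "G" * 6 + rep[:2] + "A" * 100
        # donor window [92,108) = rep + GT+6T ; acceptor window [144,160)
        seq = list("C" * 200)
        d, a = 100, 150
        for i, b in enumerate(rep):
            seq[d - 8 + i] = b
            seq[a + i] = b
        g = _genome("".join(seq))
        assert detect_rt_switch(SpliceJunction("chr1", d, a, "+"), g, k=8)

    def test_longest_common_substring_oracle(self, rng):
        # brute-force LCS length on random windows decides the flag
        def lcs(a, b):
            best = 0
            for i in range(len(a)):
                for j in range(len(b)):
                    l = 0
                    while i + l < len(a) and j + l < len(b) and a[i + l] == b[j + l]:
                        l += 1
                    best = max(best, l)
            return best

        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=400))
            g = _genome(seq)
            j = SpliceJunction("chr1", 100, 300, "+")
            donor_w, accept_w = seq[92:108], seq[292:308]
            assert detect_rt_switch(j, g, k=8) == (lcs(donor_w, accept_w) >= 8)

    def test_flag_rate_monotone_in_k(self, rng):
        # a longer required repeat can only make the flag rarer; at k=1 the
        # majority of random junctions are flagged
        n_flagged = {1: 0, 2: 0, 4: 0, 8: 0}
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), size=400))
            g = _genome(seq)
            j = SpliceJunction("chr1", 100, 300, "+")
            for k in n_flagged:
                n_flagged[k] += detect_rt_switch(j, g, k=k)
        assert n_flagged[1] >= n_flagged[2] >= n_flagged[4] >= n_flagged[8]
        assert n_flagged[1] >= 50


class TestIntronRetention:
    ref = build_reference_index(
        [tx("r1", "g1", [(100, 200), (300, 400), (500, 600)])]
    )

    def test_full_retention_with_matching_chain_is_m(self):
        q = tx("q", "", [(100, 400), (500, 600)])
        assert detect_intron_retention(q, self.ref) == "m"

    def test_retention_with_mismatched_chain_is_n(self):
        q = tx("q", "", [(100, 400), (550, 600)])  # novel acceptor at 550
        assert detect_intron_retention(q, self.ref) == "n"

    def test_identical_query_is_none(self):
        q = tx("q", "", [(100, 200), (300, 400), (500, 600)])
        assert detect_intron_retention(q, self.ref) is None

    def test_mono_exon_inside_intron_is_i(self):
        q = tx("q", "", [(210, 290)])
        assert detect_intron_retention(q, self.ref) == "i"

    def test_reference_inside_query_intron_is_y(self):
        ref = build_reference_index(
            [tx("r1", "g1", [(100, 200), (300, 400), (500, 600)]),
             tx("r2", "g2", [(220, 280)])]
        )
        q = tx("q", "", [(100, 200), (500, 600)])
        # r2 sits wholly inside the query's intron; no retention vs r1
        assert detect_intron_retention(q, ref) == "y"


class TestFilterPolicy:
    def flags(self, **kw):
        f = QcFlags("t")
        for k, v in kw.items():
            setattr(f, k, v)
        return f

    def unreliable(self):
        return self.flags(
            far_from_tts=True, a_rich_downstream=True, no_polyA_db_overlap=True
        )

    def call(self, cat):
        return StructuralCall("t", cat)

    def test_fsm_kept_regardless_of_flags(self):
        f = self.unreliable()
        f.rt_switch_junctions = [SpliceJunction("chr1", 1, 10, "+")]
        f.intron_retention_code = "m"
        d = apply_filter_policy(self.call(StructuralCategory.FSM), f)
        assert d.keep and d.reasons == []

    def test_ism_dropped_only_for_unreliable_3prime(self):
        d = apply_filter_policy(self.call(StructuralCategory.ISM), self.unreliable())
        assert not d.keep and d.reasons == ["unreliable_3prime"]
        f = self.flags(intron_retention_code="m")  # not an ISM filter
        assert apply_filter_policy(self.call(StructuralCategory.ISM), f).keep

    def test_nic_dropped_for_intron_retention(self):
        f = self.flags(intron_retention_code="m")
        d = apply_filter_policy(self.call(StructuralCategory.NIC), f)
        assert not d.keep and d.reasons == ["intron_retention"]

    def test_nnc_dropped_for_noncanonical(self):
        f = self.flags(noncanonical_junctions=[SpliceJunction("chr1", 1, 10, "+")])
        d = apply_filter_policy(self.call(StructuralCategory.NNC), f)
        assert not d.keep and d.reasons == ["noncanonical"]
        # NIC does not carry the canonical filter
        assert apply_filter_policy(self.call(StructuralCategory.NIC), f).keep

    def test_other_categories_skip_3prime_filter(self):
        for cat in (
            StructuralCategory.ANTISENSE,
            StructuralCategory.INTERGENIC,
            StructuralCategory.FUSION,
        ):
            assert apply_filter_policy(self.call(cat), self.unreliable()).keep

    def test_keep_iff_no_reasons(self):
        f = self.unreliable()
        f.junction_short_read_coverage = {(1, 10): 0}
        d = apply_filter_policy(self.call(StructuralCategory.NNC), f)
        assert not d.keep and set(d.reasons) == {"unreliable_3prime", "coverage"}

    def test_relaxing_thresholds_never_shrinks_kept_set(self, planted, ref_index):
        calls, _ = classify_catalog(planted.queries, ref_index)
        strict = QcConfig()
        loose = QcConfig(min_coverage=0, tts_distance=10**9)
        kept_strict, kept_loose = set(), set()
        for q, call in zip(planted.queries, calls):
            f = compute_qc_flags(q, planted.genome, ref_index, planted.polya_db,
                                 planted.coverage, 1, strict)
            if apply_filter_policy(call, f, strict).keep:
                kept_strict.add(q.transcript_id)
            f2 = compute_qc_flags(q, planted.genome, ref_index, planted.polya_db,
                                  planted.coverage, 1, loose)
            if apply_filter_policy(call, f2, loose).keep:
                kept_loose.add(q.transcript_id)
        assert kept_strict <= kept_loose


class TestEndValidation:
    def test_tss_supported_by_cage_peak(self, planted, ref_index):
        t = planted.reference[0]
        cage = PeakIndex()
        cage.add("chr1", t.tss - 5, t.tss + 5)
        sup = validate_ends(t, cage, None, None, planted.genome)
        assert sup.tss_supported

    def test_polya_motif_supports_tts(self):
        g = _genome("C" * 100 + "AATAAA" + "C" * 18 + "G" * 100)
        t = tx("q", "", [(50, 124)])
        sup = validate_ends(t, None, None, None, g)
        assert sup.tts_supported and not sup.tss_supported

    def test_no_peaks_no_motif_unsupported(self):
        g = _genome("C" * 400)
        t = tx("q", "", [(50, 150)])
        sup = validate_ends(t, None, None, None, g)
        assert not sup.tss_supported and not sup.tts_supported

    def test_support_rates(self):
        calls = [StructuralCall(f"t{i}", StructuralCategory.NIC) for i in range(10)]
        sups = [EndSupport(f"t{i}", i < 3, i < 3) for i in range(10)]
        rep = support_rate_report(calls, sups)
        assert rep.loc["NIC", "supported_rate"] == pytest.approx(0.3)
        assert "FSM" not in rep.index  # empty category is missing, not zero
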