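import re

import numpy as np
import pytest

from sgrnakit import library_design as ld
from sgrnakit.guide_features import SgrnaCandidate, revcomp
from sgrnakit.intervals import Interval
from sgrnakit.offtarget import StringencyTier


def make_candidate(pam=1000, strand="+", proto="ACATCATCATCATCAATCA",
                   gene="GENEA", tss="GENEA:P1"):
    return SgrnaCandidate(
        id=f"{gene}_{strand}{pam}", gene=gene, tss_id=tss, chrom="chr1",
        strand=strand, pam_3g_coord=pam, protospacer_genomic=proto,
        expression_seq="G" + proto,
    )


def sel(pam=1000, predicted=0.5, tier=StringencyTier.T0, empirical=None,
        distance=1000.0, strand="+", proto="ACATCATCATCATCAATCA"):
    return ld.SelectionCandidate(
        candidate=make_candidate(pam=pam, strand=strand, proto=proto),
        predicted_score=predicted, tier=tier,
        empirical_score=empirical, tss_distance=distance,
    )


class TestFormatOligo:
    def test_oligo_is_84_bp(self):
        oligo = ld.format_oligo("G" + "ACATCATCATCATCAATCA")
        assert len(oligo.sequence) == 84

    def test_round_trip_between_arms(self):
        expr = "G" + "ACATCATCATCATCAATCA"
        oligo = ld.format_oligo(expr)
        seq = oligo.sequence
        start = seq.index(ld.BSTXI_ARM) + len(ld.BSTXI_ARM)
        assert seq[start:start + 20] == expr

    def test_expression_seq_starts_at_template_position_30(self):
        # index arithmetic on the template: 18 (adapter) + 11 (arm) = 29,
        # so the leading G is 1-based position 30
        oligo = ld.format_oligo("G" + "ACATCATCATCATCAATCA")
        assert oligo.sequence[29] == "G"
        assert oligo.sequence[29:49] == oligo.insert

    def test_wrong_adapter_length_raises(self):
        with pytest.raises(ValueError, match="adapters"):
            ld.format_oligo("G" + "A" * 19, adapter5="ACGT", adapter3="ACGT")

    def test_wrong_insert_length_raises(self):
        with pytest.raises(ValueError):
            ld.format_oligo("A" * 19)


def oracle_forbidden(oligo):
    """Exhaustive scan oracle: every restriction-site match on either strand,
    minus the two intended arm spans."""
    seq = oligo.sequence
    pats = {"CCANNNNNNTGG", "GCTNAGC", "CCTGCAGG"}
    spans = set()
    for pat in pats:
        regex = pat.replace("N", "[ACGT]")
        for s in (seq, revcomp(seq)):
            for i in range(len(s)):
                m = re.match(regex, s[i:])
                if m:
                    a, b = i, i + m.end()
                    if s is not seq:
                        a, b = len(seq) - b, len(seq) - a
                    spans.add((a, b))
    allowed = ld.intended_site_spans(len(oligo.adapter5))
    return bool(spans - allowed)


class TestForbiddenSites:
    def test_sbfi_in_insert_flagged(self):
        oligo = ld.format_oligo("G" + "AAAA" + "CCTGCAGG" + "AAAAAAA")
        assert ld.has_forbidden_site(oligo)

    def test_clean_insert_not_flagged(self):
        oligo = ld.format_oligo("G" + "ACATCATCATCATCAATCA")
        assert not ld.has_forbidden_site(oligo)

    def test_sbfi_across_insert_arm_junction_flagged(self):
        # insert ends with CCTGCAG; the BlpI arm's leading G completes SbfI
        insert = "G" + "A" * 12 + "CCTGCAG"
        assert len(insert) == 20
        oligo = ld.format_oligo(insert)
        assert ld.has_forbidden_site(oligo)

    def test_matches_exhaustive_oracle(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(300):
            insert = "G" + "".join(bases[rng.integers(0, 4, 19)])
            oligo = ld.format_oligo(insert)
            assert ld.has_forbidden_site(oligo) == oracle_forbidden(oligo)


class TestSelectSgrnas:
    def test_empirical_first_regardless_of_predicted(self):
        pool = [sel(pam=1000, predicted=0.1, empirical=0.8)]
        pool += [sel(pam=1000 + 10 * i, predicted=0.9) for i in range(1, 10)]
        result = ld.select_sgrnas(pool, "GENEA:P1")
        assert result.targeted
        first = result.entries[0]
        assert first.source is ld.Source.EMPIRICAL
        assert first.pam_3g_coord == 1000
        assert first.selection_rank == 1

    def test_at_most_two_empirical_then_bonus(self):
        # 3 qualifying empirical guides: the 3rd competes with +0.2
        pool = [
            sel(pam=1000, predicted=0.1, empirical=0.9),
            sel(pam=1010, predicted=0.1, empirical=0.85),
            sel(pam=1020, predicted=0.5, empirical=0.8),
            sel(pam=1030, predicted=0.6),
        ]
        pool += [sel(pam=1040 + 10 * i, predicted=0.3) for i in range(6)]
        result = ld.select_sgrnas(pool, "GENEA:P1")
        entries = result.entries
        assert [e.source for e in entries[:2]] == [ld.Source.EMPIRICAL] * 2
        # 3rd empirical (0.5 + 0.2 = 0.7) outranks the 0.6 pure-predicted guide
        assert entries[2].pam_3g_coord == 1020
        assert entries[2].source is ld.Source.PREDICTED
        assert entries[2].score == pytest.approx(0.7)
        assert entries[3].pam_3g_coord == 1030

    def test_empirical_below_threshold_not_prioritized(self):
        pool = [sel(pam=1000, predicted=0.1, empirical=0.7)]
        pool += [sel(pam=1000 + 10 * i, predicted=0.9) for i in range(1, 11)]
        result = ld.select_sgrnas(pool, "GENEA:P1")
        assert result.entries[0].source is ld.Source.PREDICTED

    def test_empirical_too_far_not_prioritized(self):
        pool = [sel(pam=1000, predicted=0.1, empirical=0.9, distance=6000)]
        pool += [sel(pam=1000 + 10 * i, predicted=0.9) for i in range(1, 11)]
        result = ld.select_sgrnas(pool, "GENEA:P1")
        assert result.entries[0].source is ld.Source.PREDICTED

    def test_3bp_shift_exclusion(self):
        pool = [
            sel(pam=1000, predicted=0.9),
            sel(pam=1002, predicted=0.8),  # only 2 bp shifted: skipped
            sel(pam=1003, predicted=0.7),  # exactly 3 bp: allowed
        ]
        pool += [sel(pam=1010 + 10 * i, predicted=0.5) for i in range(8)]
        result = ld.select_sgrnas(pool, "GENEA:P1")
        pams = {e.pam_3g_coord for e in result.entries}
        assert 1000 in pams and 1003 in pams and 1002 not in pams

    def test_opposite_strand_sites_never_overlap(self):
        pool = [
            sel(pam=1000, predicted=0.9),
            sel(pam=1001, predicted=0.8, strand="-"),
        ]
        pool += [sel(pam=1010 + 10 * i, predicted=0.5) for i in range(8)]
        result = ld.select_sgrnas(pool, "GENEA:P1")
        assert len(result.entries) == 10
        assert any(e.strand == "-" for e in result.entries)

    def test_tier_relaxation_fills_to_ten(self):
        # hand-executed oracle: 8 T0 guides fill first, then the two T1
        pool = [sel(pam=1000 + 10 * i, predicted=0.8 - 0.01 * i) for i in range(8)]
        pool += [
            sel(pam=1100, predicted=0.99, tier=StringencyTier.T1),
            sel(pam=1110, predicted=0.98, tier=StringencyTier.T1),
        ]
        result = ld.select_sgrnas(pool, "GENEA:P1")
        assert result.targeted
        tiers = [e.tier for e in result.entries]
        assert tiers.count(StringencyTier.T0) == 8
        assert tiers.count(StringencyTier.T1) == 2
        # despite higher predicted scores, T1 guides rank after all T0 guides
        assert [e.tier for e in result.entries[:8]] == [StringencyTier.T0] * 8

    def test_fail_tier_never_selected(self):
        pool = [sel(pam=1000 + 10 * i, predicted=0.5) for i in range(10)]
        pool += [sel(pam=1200, predicted=0.99, tier=StringencyTier.FAIL)]
        result = ld.select_sgrnas(pool, "GENEA:P1")
        assert all(e.tier is not StringencyTier.FAIL for e in result.entries)
        assert all(e.pam_3g_coord != 1200 for e in result.entries)

    def test_untargetable_tss(self):
        pool = [sel(pam=1000 + 10 * i, predicted=0.5) for i in range(7)]
        result = ld.select_sgrnas(pool, "GENEA:P1")
        assert not result.targeted
        assert result.entries == []
        assert "7 of 10" in result.reason

    def test_partial_allowed_when_not_required_full(self):
        pool = [sel(pam=1000 + 10 * i, predicted=0.5) for i in range(7)]
        result = ld.select_sgrnas(pool, "GENEA:P1", require_full=False)
        assert result.targeted
        assert len(result.entries) == 7

    def test_ranks_unique_and_halves(self):
        pool = [sel(pam=1000 + 10 * i, predicted=0.5) for i in range(12)]
        result = ld.select_sgrnas(pool, "GENEA:P1")
        ranks = [e.selection_rank for e in result.entries]
        assert ranks == list(range(1, 11))
        assert [e.half for e in result.entries[:5]] == [ld.Half.TOP5] * 5
        assert [e.half for e in result.entries[5:]] == [ld.Half.SECOND5] * 5

    def test_deterministic_tie_break(self):
        pool = [sel(pam=p, predicted=0.5) for p in (1050, 1000, 1100)]
        pool += [sel(pam=1200 + 10 * i, predicted=0.4) for i in range(7)]
        a = ld.select_sgrnas(pool, "GENEA:P1")
        b = ld.select_sgrnas(pool[::-1], "GENEA:P1")
        assert [e.sgrna_id for e in a.entries] == [e.sgrna_id for e in b.entries]
        assert [e.pam_3g_coord for e in a.entries[:3]] == [1000, 1050, 1100]

    def test_no_two_entries_within_2bp(self):
        pool = [sel(pam=1000 + i, predicted=0.5) for i in range(40)]
        result = ld.select_sgrnas(pool, "GENEA:P1")
        coords = sorted(e.pam_3g_coord for e in result.entries)
        assert all(b - a >= 3 for a, b in zip(coords, coords[1:]))


class TestNegativeControls:
    def _library(self, rng, n=40):
        bases = np.array(list("ACGT"))
        entries = []
        for i in range(n):
            proto = "".join(bases[rng.integers(0, 4, 19)])
            entries.append(
                ld.LibraryEntry(
                    sgrna_id=f"sg{i}", gene="G", tss_id="G:P1", chrom="chr1",
                    strand="+", pam_3g_coord=1000 + 10 * i, protospacer=proto,
                    expression_seq="G" + proto, source=ld.Source.PREDICTED,
                    selection_rank=(i % 10) + 1, score=0.5,
                    tier=StringencyTier.T0,
                    half=ld.Half.TOP5 if (i % 10) < 5 else ld.Half.SECOND5,
                )
            )
        return entries

    def test_frequency_matching(self, rng):
        library = self._library(rng)
        genome = {"chr1": "T" * 500}  # no NGG/CCN sites at all
        controls = ld.generate_negative_controls(library, 1000, genome, {}, seed=1)
        freqs = ld.protospacer_base_frequencies(controls)
        target = ld.protospacer_base_frequencies([e.protospacer for e in library])
        assert np.abs(freqs - target).max() <= 0.05

    def test_seed_reproducible(self, rng):
        library = self._library(rng)
        genome = {"chr1": "T" * 500}
        a = ld.generate_negative_controls(library, 50, genome, {}, seed=9)
        b = ld.generate_negative_controls(library, 50, genome, {}, seed=9)
        assert a == b

    def test_genomic_match_rejected(self, rng):
        # degenerate library: every sample is the planted protospacer, which
        # has a perfect genomic site, so generation must abort
        proto = "ACATCATCATCATCAATCA"
        entries = self._library(rng, n=5)
        entries = [
            ld.LibraryEntry(
                sgrna_id=e.sgrna_id, gene=e.gene, tss_id=e.tss_id, chrom=e.chrom,
                strand=e.strand, pam_3g_coord=e.pam_3g_coord, protospacer=proto,
                expression_seq="G" + proto, source=e.source,
                selection_rank=e.selection_rank, score=e.score, tier=e.tier,
                half=e.half,
            )
            for e in entries
        ]
        genome = {"chr1": "T" * 100 + proto + "TGG" + "T" * 100}
        with pytest.raises(ld.NegativeControlError):
            ld.generate_negative_controls(entries, 5, genome, {}, seed=0,
                                          max_attempts_factor=10)


class TestPartition:
    def _entries(self, rng):
        pool = [sel(pam=1000 + 10 * i, predicted=0.5) for i in range(12)]
        e1 = ld.select_sgrnas(pool, "GENEA:P1").entries
        pool2 = [
            ld.SelectionCandidate(
                candidate=make_candidate(pam=3000 + 10 * i, gene="GENEB",
                                         tss="GENEB:P1"),
                predicted_score=0.4, tier=StringencyTier.T0,
            )
            for i in range(12)
        ]
        e2 = ld.select_sgrnas(pool2, "GENEB:P1").entries
        return e1 + e2

    def test_group_and_half_labels(self, rng):
        entries = self._entries(rng)
        labeled = ld.partition_sublibraries(entries, {"GENEA": "grp1", "GENEB": "grp2"})
        groups = {e.sublibrary for e in labeled}
        assert groups == {"grp1", "grp2"}
        for e in labeled:
            assert e.half is (ld.Half.TOP5 if e.selection_rank <= 5 else ld.Half.SECOND5)

    def test_counts_sum_to_library_size(self, rng):
        entries = self._entries(rng)
        labeled = ld.partition_sublibraries(entries, {"GENEA": "grp1", "GENEB": "grp2"})
        from collections import Counter

        counts = Counter(e.sublibrary for e in labeled)
        assert sum(counts.values()) == len(entries)

    def test_missing_gene_unassigned_with_warning(self, rng):
        entries = self._entries(rng)
        with pytest.warns(UserWarning, match="missing"):
            labeled = ld.partition_sublibraries(entries, {"GENEA": "grp1"})
        assert {e.sublibrary for e in labeled if e.gene == "GENEB"} == {"unassigned"}

    def test_stable_under_rerun(self, rng):
        entries = self._entries(rng)
        a = ld.partition_sublibraries(entries, {"GENEA": "g", "GENEB": "h"})
        b = ld.partition_sublibraries(entries, {"GENEA": "g", "GENEB": "h"})
        assert a == b
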