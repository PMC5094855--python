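import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sgrnakit import screen_scoring as ss


def count_table(t0, end, doublings=10.0):
    """Single-replicate count table from {sgrna_id: count} dicts."""
    return ss.make_count_table({"rep1": t0}, {"rep1": end}, {"rep1": doublings})


class TestCountProtospacers:
    def fastq(self, seqs):
        lines = []
        for i, s in enumerate(seqs):
            lines += [f"@read{i}", s, "+", "I" * len(s)]
        return lines

    def test_exact_matches_counted(self):
        expr = {"sg1": "G" + "ACATCATCATCATCAATCA"}
        reads = self.fastq([expr["sg1"] + "TTTT"] * 3)
        counts, unmatched = ss.count_protospacers(reads, expr)
        assert counts["sg1"] == 3
        assert unmatched == 0

    def test_mismatch_unmatched(self):
        expr = {"sg1": "G" + "ACATCATCATCATCAATCA"}
        bad = "G" + "ACATCATCATCATCAATCT"
        counts, unmatched = ss.count_protospacers(self.fastq([bad]), expr)
        assert counts["sg1"] == 0
        assert unmatched == 1

    def test_empty_fastq(self):
        expr = {"sg1": "G" + "A" * 19}
        counts, unmatched = ss.count_protospacers([], expr)
        assert counts["sg1"] == 0 and unmatched == 0

    def test_offset(self):
        expr = {"sg1": "G" + "ACATCATCATCATCAATCA"}
        reads = self.fastq(["TT" + expr["sg1"]])
        counts, _ = ss.count_protospacers(reads, expr, offset=2)
        assert counts["sg1"] == 1

    def test_offset_beyond_read_raises(self):
        expr = {"sg1": "G" + "A" * 19}
        with pytest.raises(ValueError, match="offset"):
            ss.count_protospacers(self.fastq(["ACGT"]), expr, offset=10)


def base_counts(n_targeting=20, n_nt=10, t0=1000):
    ids = [f"sg{i}" for i in range(n_targeting)] + [f"nt{i}" for i in range(n_nt)]
    t0_map = {i: t0 for i in ids}
    end_map = {i: t0 for i in ids}
    return ids, t0_map, end_map


class TestComputeGamma:
    def test_count_filter_both_below(self):
        ids, t0, end = base_counts()
        t0["sg0"], end["sg0"] = 49, 30    # both < 50: excluded
        t0["sg1"], end["sg1"] = 49, 200   # one >= 50: retained
        table = count_table(t0, end)
        phen = ss.compute_gamma(table, [f"nt{i}" for i in range(10)])
        assert "sg0" not in phen.gammas.index
        assert "sg1" in phen.gammas.index

    def test_nontargeting_median_exactly_zero(self, rng):
        # odd control count: the median is one value, subtraction is exact
        ids, t0, end = base_counts(n_nt=11)
        for i in ids:
            end[i] = int(rng.integers(500, 2000))
        table = count_table(t0, end)
        nt = [f"nt{i}" for i in range(11)]
        phen = ss.compute_gamma(table, nt)
        assert phen.gammas.loc[nt, "rep1"].median() == 0.0

    def test_nontargeting_median_zero_even_count(self, rng):
        ids, t0, end = base_counts(n_nt=10)
        for i in ids:
            end[i] = int(rng.integers(500, 2000))
        phen = ss.compute_gamma(count_table(t0, end), [f"nt{i}" for i in range(10)])
        assert abs(phen.gammas.loc[[f"nt{i}" for i in range(10)], "rep1"].median()) < 1e-15

    def test_behaves_like_nt_median_gamma_zero(self):
        ids, t0, end = base_counts()
        table = count_table(t0, end)
        phen = ss.compute_gamma(table, [f"nt{i}" for i in range(10)])
        # every sgRNA behaves exactly like the NT median here
        assert np.allclose(phen.gammas["rep1"], 0.0)

    def test_doublings_scale_gamma(self, rng):
        ids, t0, end = base_counts()
        for i in ids:
            end[i] = int(rng.integers(200, 5000))
        nt = [f"nt{i}" for i in range(10)]
        g1 = ss.compute_gamma(count_table(t0, end, doublings=10.0), nt)
        g2 = ss.compute_gamma(count_table(t0, end, doublings=20.0), nt)
        np.testing.assert_allclose(
            g1.gammas["rep1"].to_numpy(), 2 * g2.gammas["rep1"].to_numpy()
        )

    def test_zero_depth_raises(self):
        ids, t0, end = base_counts()
        end = {i: 0 for i in ids}
        t0 = {i: 100 for i in ids}
        with pytest.raises(ValueError, match="depth"):
            ss.compute_gamma(count_table(t0, end), [f"nt{i}" for i in range(10)])

    def test_unknown_nt_id_raises(self):
        ids, t0, end = base_counts()
        with pytest.raises(ValueError, match="non-targeting"):
            ss.compute_gamma(count_table(t0, end), ["missing"])


def permutation_mw_p(group, controls):
    """Exhaustive two-sided permutation p for the Mann-Whitney U statistic."""
    combined = np.r_[group, controls]
    n1 = len(group)
    u_obs = stats.mannwhitneyu(group, controls, alternative="two-sided").statistic
    n1n2 = n1 * len(controls)
    # two-sided: as-or-more-extreme on either tail of the symmetric U range
    dev_obs = abs(u_obs - n1n2 / 2)
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(combined)), n1):
        g = combined[list(idx)]
        c = np.delete(combined, list(idx))
        u = stats.mannwhitneyu(g, c, alternative="two-sided").statistic
        if abs(u - n1n2 / 2) >= dev_obs - 1e-9:
            count += 1
        total += 1
    return count / total


class TestGeneScoring:
    def phen(self, gammas, nt_gammas):
        idx = [f"sg{i}" for i in range(len(gammas))] + \
              [f"nt{i}" for i in range(len(nt_gammas))]
        values = list(gammas) + list(nt_gammas)
        df = pd.DataFrame({"rep1": values, "mean": values}, index=idx)
        return ss.GrowthPhenotypes(df, [f"nt{i}" for i in range(len(nt_gammas))])

    def test_top3_mean_phenotype(self):
        phen = self.phen([-1.0, -0.9, -0.2, 0.1, 0.0], [0.0, 0.01, -0.01])
        gmap = {f"sg{i}": ("G1", "G1:P1") for i in range(5)}
        (score,) = ss.score_genes(phen, gmap)
        assert score.phenotype == pytest.approx((-1.0 - 0.9 - 0.2) / 3)

    def test_mann_whitney_matches_permutation_oracle(self, rng):
        group = rng.normal(0.5, 1, 4)
        controls = rng.normal(0, 1, 5)
        p = ss.mann_whitney_p(group, controls)
        assert p == pytest.approx(permutation_mw_p(group, controls))

    def test_mann_whitney_oracle_various_sizes(self, rng):
        for n1, n2 in [(3, 5), (4, 4), (5, 8), (8, 6)]:
            group = rng.normal(1, 1, n1)
            controls = rng.normal(0, 1, n2)
            p = ss.mann_whitney_p(group, controls)
            assert p == pytest.approx(permutation_mw_p(group, controls)), (n1, n2)

    def test_multi_tss_lowest_p_reported(self, rng):
        strong = list(rng.normal(-2, 0.1, 5))
        weak = list(rng.normal(-0.1, 0.1, 5))
        nt = list(rng.normal(0, 0.1, 20))
        phen = self.phen(strong + weak, nt)
        gmap = {f"sg{i}": ("G1", "G1:P1" if i < 5 else "G1:P2") for i in range(10)}
        (score,) = ss.score_genes(phen, gmap)
        assert score.tss_id == "G1:P1"

    def test_no_controls_raises(self):
        phen = self.phen([-1.0, -0.5, -0.2], [])
        with pytest.raises(ValueError):
            ss.score_genes(phen, {"sg0": ("G1", "G1:P1")})

    def test_min_achievable_p_floor(self):
        floor = ss.min_achievable_p(10, 50)
        assert 0 < floor < 1e-3
        assert ss.mann_whitney_p(np.arange(10), np.arange(100, 150)) >= floor


class TestNcGenes:
    def test_seeded_sampling_identical(self):
        a = ss.make_nc_genes([f"nt{i}" for i in range(20)], 5, seed=3)
        b = ss.make_nc_genes([f"nt{i}" for i in range(20)], 5, seed=3)
        assert a == b

    def test_sampling_with_replacement(self):
        genes = ss.make_nc_genes(["nt0", "nt1"], 50, size=10, seed=0)
        assert any(len(set(g.member_ids)) < 10 for g in genes)

    def test_null_phenotypes_centered_at_zero(self, rng):
        nt_ids = [f"nt{i}" for i in range(500)]
        values = rng.normal(0, 0.05, 500)
        df = pd.DataFrame({"rep1": values, "mean": values}, index=nt_ids)
        phen = ss.GrowthPhenotypes(df, nt_ids)
        nc = ss.make_nc_genes(nt_ids, 200, seed=1)
        scores = ss.score_nc_genes(phen, nc)
        mean_phen = np.mean([s.phenotype for s in scores])
        assert abs(mean_phen) < 0.05

    def test_empty_nt_pool_raises(self):
        with pytest.raises(ValueError):
            ss.make_nc_genes([], 5)


class TestCallHits:
    def gene_score(self, gene, z, p):
        return ss.GeneScore(gene=gene, tss_id=f"{gene}:P1", phenotype=z,
                            p_value=p, n_sgrnas=10, z=z,
                            hit_score=z * -math.log10(p))

    def test_printed_arithmetic(self):
        s = self.gene_score("G1", -5.0, 1e-2)
        assert abs(s.hit_score) == pytest.approx(10.0)
        nc = [self.gene_score(f"nc{i}", 0.1, 0.5) for i in range(10)]
        result = ss.call_hits([s], nc, threshold=10.0)
        assert result["hits"] == ["G1"]

    def test_infinite_threshold_empty(self):
        genes = [self.gene_score(f"G{i}", -5.0, 1e-4) for i in range(5)]
        nc = [self.gene_score(f"nc{i}", 0.1, 0.5) for i in range(5)]
        result = ss.call_hits(genes, nc, threshold=math.inf)
        assert result["hits"] == []

    def test_directional_calls(self):
        neg = self.gene_score("G1", -5.0, 1e-3)
        pos = self.gene_score("G2", 5.0, 1e-3)
        nc = [self.gene_score(f"nc{i}", 0.1, 0.5) for i in range(5)]
        down = ss.call_hits([neg, pos], nc, threshold=10.0, direction="negative")
        assert down["hits"] == ["G1"]
        up = ss.call_hits([neg, pos], nc, threshold=10.0, direction="positive")
        assert up["hits"] == ["G2"]

    def test_calibrated_threshold_bounds_nc_rate(self, rng):
        genes = [self.gene_score(f"G{i}", -6.0, 1e-4) for i in range(50)]
        nc = [self.gene_score(f"nc{i}", z, 10 ** -abs(rng.normal(0, 1)))
              for i, z in enumerate(rng.normal(0, 1, 1000))]
        result = ss.call_hits(genes, nc, threshold=None, target_nc_rate=0.01)
        assert result["nc_pass_rate"] <= 0.01

    def test_no_nc_genes_warns(self):
        genes = [self.gene_score("G1", -5.0, 1e-3)]
        with pytest.warns(UserWarning, match="FDR"):
            result = ss.call_hits(genes, [], threshold=10.0)
        assert math.isnan(result["empirical_fdr"])


def quadratic_pr(labels, scores):
    """O(n^2)-ish reference: precision/recall at every distinct threshold."""
    pairs = sorted(zip(scores, labels), key=lambda t: -t[0])
    out = []
    for thr in sorted({s for s, _ in pairs}, reverse=True):
        pred = [(s, l) for s, l in pairs if s >= thr]
        tp = sum(1 for _, l in pred if l)
        out.append((tp / sum(labels), tp / len(pred)))
    return out


class TestEvaluateScreen:
    def build(self, rng, n_ess=30, n_non=30, sep=3.0):
        ess_ids = [f"e{i}" for i in range(n_ess * 5)]
        non_ids = [f"n{i}" for i in range(n_non * 5)]
        nt_ids = [f"nt{i}" for i in range(50)]
        gammas = {}
        gmap = {}
        for i, sid in enumerate(ess_ids):
            gammas[sid] = rng.normal(-sep * 0.1, 0.02)
            gmap[sid] = (f"ESS{i // 5}", f"ESS{i // 5}:P1")
        for i, sid in enumerate(non_ids):
            gammas[sid] = rng.normal(0, 0.02)
            gmap[sid] = (f"NON{i // 5}", f"NON{i // 5}:P1")
        for sid in nt_ids:
            gammas[sid] = rng.normal(0, 0.02)
        values = pd.Series(gammas)
        df = pd.DataFrame({"rep1": values, "mean": values})
        phen = ss.GrowthPhenotypes(df, nt_ids)
        genes = ss.score_genes(phen, gmap)
        essential = {f"ESS{i}" for i in range(n_ess)}
        nonessential = {f"NON{i}" for i in range(n_non)}
        return phen, genes, gmap, essential, nonessential

    def test_perfect_separation(self, rng):
        phen, genes, gmap, ess, non = self.build(rng, sep=10.0)
        result = ss.evaluate_screen(phen, genes, gmap, ess, non)
        assert result["sgrna_roc_auc"] == pytest.approx(1.0)
        assert result["recall_at_precision"] == pytest.approx(1.0)
        assert result["active_sgrna_fraction"] > 0.9

    def test_random_gamma_null_auc(self, rng):
        labels = np.r_[np.ones(1000, bool), np.zeros(1000, bool)]
        scores = rng.normal(size=2000)
        from sgrnakit.activity_model import roc_auc

        assert roc_auc(labels, scores) == pytest.approx(0.5, abs=0.03)

    def test_pr_matches_quadratic_reference(self, rng):
        labels = rng.random(80) < 0.5
        if not labels.any():
            labels[0] = True
        scores = np.round(rng.normal(size=80), 1)
        recall, precision = ss.precision_recall_points(labels, scores)
        expected = quadratic_pr(labels, scores)
        got = list(zip(recall.tolist(), precision.tolist()))
        assert got == pytest.approx(expected)

    def test_average_precision_vs_reference(self, rng):
        labels = rng.random(100) < 0.3
        labels[:3] = True
        scores = rng.normal(size=100)
        ap = ss.average_precision(labels, scores)
        # reference: sum over positives of precision at their rank
        order = np.argsort(-scores)
        l = labels[order]
        ref = np.mean([
            l[:k + 1].sum() / (k + 1) for k in range(len(l)) if l[k]
        ])
        assert ap == pytest.approx(ref)

    def test_overlapping_gene_sets_raise(self, rng):
        phen, genes, gmap, ess, non = self.build(rng)
        with pytest.raises(ValueError, match="overlap"):
            ss.evaluate_screen(phen, genes, gmap, ess, ess)

    def test_empty_gene_set_raises(self, rng):
        phen, genes, gmap, ess, non = self.build(rng)
        with pytest.raises(ValueError):
            ss.evaluate_screen(phen, genes, gmap, set(), non)
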