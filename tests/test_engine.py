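import math

import numpy as np
import pytest

from conftest import brute_force_optimum, random_hitlist, random_profile, tail_sum
from ppprofiler.engine import (
    BoundTable,
    binom_tail,
    log10_binom_tail,
    make_bound_table,
    optimal_hmm_cutoff,
    score_gene,
    score_genome,
)
from ppprofiler.hitlists import HitList, HitRecord
from ppprofiler.profiles import Profile, ProfileError


def make_hitlist(bits_by_taxon, sig_field="evalue"):
    """Hit list hitting the given taxa in order, E-values 1e-50, 1e-49, ..."""
    hits = [
        HitRecord("g", f"s{i}", taxon, 10.0 ** (-50 + i), 100.0 - i)
        for i, taxon in enumerate(bits_by_taxon)
    ]
    return HitList("g", hits, sig_field).normalized()


class TestBinomTail:
    def test_zero_matches_tail_is_one(self):
        assert binom_tail(0, 5, 0.3) == 1.0

    def test_small_tail_by_hand(self):
        # P(X >= 2), X ~ Bin(3, 1/2): 3/8 + 1/8
        assert binom_tail(2, 3, 0.5) == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "h, j, expected",
        [(66, 66, 26.26), (59, 59, 23.48), (32, 32, 12.73), (19, 19, 7.56),
         (16, 16, 6.37), (18, 20, 5.30), (15, 16, 4.97), (12, 12, 4.78),
         (7, 7, 2.79)],
    )
    def test_sporadic_family_scores_at_p04(self, h, j, expected):
        """Scores of the phosphorothioation-system families at p = 0.4."""
        assert round(-log10_binom_tail(h, j, 0.4), 2) == expected

    def test_agrees_with_summation_oracle(self):
        for p in (0.048, 0.25, 0.5):
            for j in range(1, 26):
                for h in range(j + 1):
                    expected = tail_sum(h, j, p)
                    assert binom_tail(h, j, p) == pytest.approx(
                        expected, rel=1e-10
                    )

    def test_monotone_in_matches(self):
        for h in range(20):
            assert binom_tail(h + 1, 20, 0.3) <= binom_tail(h, 20, 0.3)

    def test_log_space_reaches_tiny_tails(self):
        # a perfect 200-deep prefix at p ~ 0.136 prints a score near 173
        lp = log10_binom_tail(200, 200, 200 / 1466)
        assert -lp == pytest.approx(200 * -math.log10(200 / 1466))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            binom_tail(3, 2, 0.5)
        with pytest.raises(ValueError):
            binom_tail(1, 2, 1.0)


class TestScoreGene:
    def test_perfect_prefix_closed_form(self):
        """28 positives seen first, prior overridden to 0.2: the optimum is
        the full prefix and the score is 28 * -log10(0.2)."""
        t1 = list(range(1, 29))
        t0 = list(range(29, 120))
        profile = Profile({**{t: 1 for t in t1}, **{t: 0 for t in t0}})
        hl = make_hitlist(t1 + t0[:20])
        gs = score_gene(hl, profile, prior_override=0.2)
        assert (gs.j_star, gs.h_star) == (28, 28)
        assert round(gs.score, 2) == 19.57
        assert gs.score == pytest.approx(28 * -math.log10(0.2))

    def test_empty_hitlist_scores_zero(self):
        gs = score_gene(HitList("g", []), Profile({1: 1, 2: 0}))
        assert (gs.score, gs.j_star, gs.h_star) == (0.0, 0, 0)
        assert gs.last_true_sig is None and gs.first_false_sig is None

    def test_non_profile_taxa_are_invisible(self):
        profile = Profile({1: 1, 2: 1, 3: 0})
        with_stranger = score_gene(make_hitlist([1, 99, 2, 3]), profile)
        without = score_gene(make_hitlist([1, 2, 3]), profile)
        assert (with_stranger.j_star, with_stranger.h_star) == (
            without.j_star, without.h_star)
        assert with_stranger.score == pytest.approx(without.score)

    def test_tie_broken_toward_smallest_family(self):
        # bits 1,0,1 at p=1/2: tails 0.5, 0.75, 0.5 -> optimum at j=1
        profile = Profile({1: 1, 2: 0, 3: 1, 4: 0}, prior_override=0.5)
        gs = score_gene(make_hitlist([1, 2, 3]), profile)
        assert (gs.j_star, gs.h_star) == (1, 1)

    def test_flanking_significances(self):
        profile = Profile({1: 1, 2: 1, 3: 0, 4: 0, 5: 0, 6: 0, 7: 0})
        hl = make_hitlist([1, 2, 3])
        gs = score_gene(hl, profile)
        assert (gs.j_star, gs.h_star) == (2, 2)
        assert gs.last_true_sig == pytest.approx(1e-49)  # second hit
        assert gs.first_false_sig == pytest.approx(1e-48)  # the mismatch

    def test_exhausted_list_has_no_first_false(self):
        profile = Profile({1: 1, 2: 1, 3: 0})
        gs = score_gene(make_hitlist([1, 2]), profile)
        assert gs.first_false_sig is None

    def test_degenerate_prior_rejected(self):
        with pytest.raises(ProfileError, match="degenerate"):
            score_gene(make_hitlist([1]), Profile({1: 1, 2: 1}))

    def test_raising_prior_decreases_perfect_prefix_score(self):
        profile = Profile({t: 1 for t in range(1, 11)} | {99: 0})
        hl = make_hitlist(list(range(1, 11)))
        scores = [
            score_gene(hl, profile, prior_override=p).score
            for p in (0.1, 0.2, 0.4, 0.6)
        ]
        assert scores == sorted(scores, reverse=True)
        assert all(scores[i] > scores[i + 1] for i in range(3))

    def test_matches_brute_force_on_random_lists(self):
        rng = np.random.default_rng(17)
        taxa = list(range(1, 61))
        for _ in range(30):
            profile = random_profile(rng, taxa)
            hl = random_hitlist(rng, "g", taxa, 40)
            p = profile.prior
            exp_p, exp_j, exp_h = brute_force_optimum(hl, profile, p)
            gs = score_gene(hl, profile)
            assert (gs.j_star, gs.h_star) == (exp_j, exp_h)
            assert gs.p_star == pytest.approx(exp_p, rel=1e-9)


class TestBoundTable:
    def test_start_state_bound_is_all_matches(self):
        profile = Profile({**{t: 1 for t in range(10)},
                           **{t: 0 for t in range(10, 40)}})
        bt = make_bound_table(profile)
        assert bt.bound(0, 0) == pytest.approx(binom_tail(10, 10, 0.25))

    def test_bound_is_admissible_vs_exhaustive_completion(self):
        # bound(j, h) must not exceed the tail of any reachable state
        for p in (0.2, 0.5):
            for n_pos in (3, 5):
                bt = BoundTable(n_pos, p)
                for j in range(12):
                    for h in range(min(j, n_pos) + 1):
                        reachable = [
                            tail_sum(h + a, j + a + b, p)
                            for a in range(n_pos - h + 1)
                            for b in range(12 - j)
                        ]
                        assert bt.bound(j, h) <= min(reachable) * (1 + 1e-12)

    def test_bound_monotone_in_absorbed_mismatches(self):
        bt = BoundTable(8, 0.3)
        for h in range(8):
            bounds = [bt.log10_bound(h + miss, h) for miss in range(10)]
            assert bounds == sorted(bounds)


class TestScoreGenome:
    @pytest.fixture()
    def random_batch(self):
        rng = np.random.default_rng(23)
        taxa = list(range(1, 61))
        profile = random_profile(rng, taxa)
        lists = {
            f"g{i:03d}": random_hitlist(rng, f"g{i:03d}", taxa, 40)
            for i in range(60)
        }
        return profile, lists

    def test_early_stop_equals_exhaustive(self, random_batch):
        profile, lists = random_batch
        fast = score_genome(lists, profile, early_stop=True)
        slow = score_genome(lists, profile, early_stop=False)
        for a, b in zip(fast.scores, slow.scores):
            assert (a.gene_id, a.j_star, a.h_star) == (b.gene_id, b.j_star, b.h_star)
            assert a.log10_p_star == b.log10_p_star
            assert a.last_true_sig == b.last_true_sig
            assert a.first_false_sig == b.first_false_sig
        assert fast.metadata["early_stopped_genes"] > 0

    def test_ranked_by_score_then_gene_id(self, random_batch):
        profile, lists = random_batch
        res = score_genome(lists, profile)
        keys = [(-gs.score, gs.gene_id) for gs in res]
        assert keys == sorted(keys)

    def test_all_zero_profile_with_override_scores_zero(self):
        profile = Profile({1: 0, 2: 0, 3: 0})
        lists = {"g": make_hitlist([1, 2, 3])}
        res = score_genome(lists, profile, prior_override=0.5)
        assert all(gs.score == 0.0 and gs.j_star == 0 for gs in res)

    def test_masked_taxon_equals_deleted_hits(self, random_batch):
        from ppprofiler.profiles import mask
        profile, lists = random_batch
        victim = sorted(profile.t1)[0]
        masked = mask(profile, {victim})
        stripped = {
            g: HitList(g, [h for h in hl if h.taxon != victim]).normalized()
            for g, hl in lists.items()
        }
        res_masked = score_genome(lists, masked)
        res_stripped = score_genome(stripped, masked)
        for a, b in zip(res_masked.scores, res_stripped.scores):
            assert (a.gene_id, a.log10_p_star, a.j_star, a.h_star) == (
                b.gene_id, b.log10_p_star, b.j_star, b.h_star)

    def test_rank_collapsing_counts_genus_once(self, toy_tree):
        profile = Profile({101: 1, 102: 1, 103: 0})
        lists = {"g": make_hitlist([101, 102, 103])}
        res = score_genome(lists, profile, rank="genus", tree=toy_tree)
        gs = res.scores[0]
        # strains 101/102 fold into genus 9 (one positive), 103 stays
        assert (gs.j_star, gs.h_star) == (1, 1)
        assert res.metadata["n_positive"] == 1

    def test_rank_without_tree_rejected(self):
        with pytest.raises(ValueError, match="taxonomy tree"):
            score_genome({}, Profile({1: 1, 2: 0}), rank="genus")

    def test_output_tsv_round_trip(self, random_batch, tmp_path):
        profile, lists = random_batch
        res = score_genome(lists, profile)
        out = tmp_path / "out.tsv"
        res.to_tsv(out)
        rows = [l for l in out.read_text().splitlines() if not l.startswith("#")]
        assert len(rows) == len(res)
        top = rows[0].split("\t")
        assert top[0] == res.scores[0].gene_id
        assert float(top[1]) == round(res.scores[0].score, 2)


class TestOptimalHmmCutoff:
    def _hmm_list(self, taxa, scores):
        hits = [
            HitRecord("fam", f"g{i}", t, 1e-30, s)
            for i, (t, s) in enumerate(zip(taxa, scores))
        ]
        return HitList("fam", hits, "bitscore").normalized()

    def test_cutoff_between_family_and_rest(self):
        """Top 5 hits are the whole positive set of a 20-taxon profile:
        the optimal depth is 5 and the threshold falls between hits 5/6."""
        profile = Profile({**{t: 1 for t in range(1, 6)},
                           **{t: 0 for t in range(6, 21)}})
        hl = self._hmm_list(range(1, 9), [300, 280, 260, 240, 220, 90, 80, 70])
        res = optimal_hmm_cutoff(hl, profile)
        gs = res.gene_score
        assert (gs.j_star, gs.h_star) == (5, 5)
        assert gs.score == pytest.approx(5 * -math.log10(0.25))
        assert res.score_at_optimum == 220
        assert res.cutoff == pytest.approx((220 + 90) / 2)

    def test_single_hit_in_positive_set(self):
        profile = Profile({1: 1, 2: 0, 3: 0})
        res = optimal_hmm_cutoff(self._hmm_list([1], [200]), profile)
        assert res.gene_score.j_star == 1
        assert res.cutoff == 200  # list exhausted at the boundary

    def test_agrees_with_score_gene(self):
        rng = np.random.default_rng(31)
        taxa = list(range(1, 31))
        profile = random_profile(rng, taxa)
        hl = self._hmm_list(taxa, rng.uniform(50, 400, size=30))
        res = optimal_hmm_cutoff(hl, profile)
        gs = score_gene(hl, profile)
        assert (res.gene_score.j_star, res.gene_score.log10_p_star) == (
            gs.j_star, gs.log10_p_star)
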