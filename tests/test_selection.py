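"""Codon-model selection statistics against independent oracles."""

import itertools
import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plastidkit.codonmodel import (SENSE_CODONS, STOP_CODONS,
                                   build_rate_matrix, f3x4_frequencies,
                                   spectral_model, translate_codon,
                                   uniform_frequencies)
from plastidkit.selection import (AlignmentError, CodonAlignment,
                                  InconsistentFitError, SaturationError,
                                  UnidentifiableError, bonferroni, branch_dnds,
                                  clean_alignment, fit_site_model, lrt,
                                  ml_pairwise_dnds, ng86_dnds,
                                  tajima_relative_rate)
from plastidkit.synthetic_data import EvolSimConfig, simulate_codon_alignment


# ---------------------------------------------------------------------------
# independent oracle: recursive pathway enumeration for NG86 differences
# ---------------------------------------------------------------------------

def _oracle_pathways(c1, c2):
    """All mutational pathways as (syn, nonsyn, passes_stop), recursively."""
    if c1 == c2:
        return [(0, 0, False)]
    out = []
    for pos in range(3):
        if c1[pos] == c2[pos]:
            continue
        step = c1[:pos] + c2[pos] + c1[pos + 1:]
        stop = translate_codon(step) == "*"
        syn_step = int(translate_codon(step) == translate_codon(c1) and not stop)
        nonsyn_step = 1 - syn_step
        for s, n, b in _oracle_pathways(step, c2):
            out.append((syn_step + s, nonsyn_step + n, stop or b))
    return out


def oracle_ng86_diffs(c1, c2):
    paths = _oracle_pathways(c1, c2)
    open_paths = [(s, n) for s, n, b in paths if not b]
    use = open_paths if open_paths else [(s, n) for s, n, _ in paths]
    return (sum(s for s, _ in use) / len(use),
            sum(n for _, n in use) / len(use))


class TestCleanAlignment:
    def test_gap_free_alignment_unchanged(self):
        aln = CodonAlignment(["a", "b"], ["ATGAAA", "ATGAAG"])
        cleaned, removed = clean_alignment(aln)
        assert removed == 0
        assert cleaned.rows == aln.rows

    def test_gap_column_removed_in_all_rows(self):
        aln = CodonAlignment(["a", "b"], ["ATG---AAA", "ATGCCCAAA"])
        cleaned, removed = clean_alignment(aln)
        assert removed == 1
        assert cleaned.rows == ["ATGAAA", "ATGAAA"]

    def test_everything_removed_raises(self):
        aln = CodonAlignment(["a", "b"], ["---", "AAA"])
        with pytest.raises(AlignmentError):
            clean_alignment(aln)

    def test_internal_stop_rejected(self):
        aln = CodonAlignment(["a", "b"], ["ATGTAAAAA", "ATGAAAAAA"])
        with pytest.raises(AlignmentError, match="stop"):
            clean_alignment(aln)


class TestNG86:
    def test_identical_sequences(self):
        r = ng86_dnds(CodonAlignment(["a", "b"], ["ATGGCA", "ATGGCA"]))
        assert r.dn == 0.0 and r.ds == 0.0

    def test_single_synonymous_change_hand_computation(self):
        # 10 TTT codons, one mutated to TTC: S = 10/3, pS = 0.3,
        # dS = -(3/4) ln(1 - 4*0.3/3)
        aln = CodonAlignment(["a", "b"], ["TTT" * 10, "TTT" * 9 + "TTC"])
        r = ng86_dnds(aln)
        assert r.dn == 0.0
        assert r.syn_sites == pytest.approx(10 / 3)
        assert r.ds == pytest.approx(-0.75 * math.log(1 - 0.4), abs=1e-12)

    def test_agrees_with_biopython_where_conventions_coincide(self):
        # Biopython's NG86 averages over *all* mutational pathways; the
        # classic convention (implemented here) discards pathways passing
        # through a stop codon.  On codon pairs whose pathways never touch
        # a stop the two must agree exactly.
        from Bio.Data import CodonTable
        from Bio.codonalign.codonseq import _count_diff_NG86
        from plastidkit.selection import _pathway_changes
        table = CodonTable.generic_by_id[1]
        checked = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for c1, c2 in itertools.product(SENSE_CODONS[::2], SENSE_CODONS[::3]):
                if any(blocked for *_, blocked in _oracle_pathways(c1, c2)):
                    continue
                theirs = _count_diff_NG86(c1, c2, table)
                assert _pathway_changes(c1, c2) == \
                    pytest.approx((theirs[0], theirs[1]))
                checked += 1
        assert checked > 300

    def test_full_sequence_agrees_with_biopython_on_single_diff_codons(self):
        # single-nucleotide codon differences have one pathway, so the
        # stop-pathway convention cannot differ: whole-pipeline check
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
        rng = np.random.default_rng(5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(10):
                n = int(rng.integers(20, 60))
                codons = list(rng.choice(SENSE_CODONS, n))
                s1 = "".join(codons)
                for _ in range(int(rng.integers(1, 5))):
                    i = int(rng.integers(n))
                    variants = [c for c in SENSE_CODONS
                                if sum(a != b for a, b in zip(c, codons[i])) == 1]
                    codons[i] = variants[int(rng.integers(len(variants)))]
                s2 = "".join(codons)
                ours = ng86_dnds(CodonAlignment(["a", "b"], [s1, s2]))
                dn, ds = cal_dn_ds(CodonSeq(s1), CodonSeq(s2), method="NG86")
                assert ours.dn == pytest.approx(dn, abs=1e-9)
                assert ours.ds == pytest.approx(ds, abs=1e-9)

    def test_pathway_counts_match_recursive_oracle_exhaustively(self):
        from plastidkit.selection import _pathway_changes
        for c1, c2 in itertools.product(SENSE_CODONS[::5], SENSE_CODONS[::7]):
            assert _pathway_changes(c1, c2) == \
                pytest.approx(oracle_ng86_diffs(c1, c2))

    def test_saturation_raises(self):
        # every codon maximally different at synonymous positions
        aln = CodonAlignment(["a", "b"], ["CGA" * 30, "AGG" * 30])
        with pytest.raises(SaturationError):
            ng86_dnds(aln)


class TestMLPairwise:
    def test_recovers_simulated_omega(self):
        cfg = EvolSimConfig(tree="(A:0.25,B:0.25);", n_codons=1000, kappa=2.0,
                            site_classes=[(1.0, 0.5)], seed=1)
        aln, _ = simulate_codon_alignment(cfg)
        fit = ml_pairwise_dnds(aln, seed=1)
        assert fit.omega == pytest.approx(0.5, abs=0.1)
        assert fit.lnl_free >= fit.lnl_fixed
        assert fit.se_omega is not None and fit.se_omega > 0

    def test_agrees_with_counting_at_low_divergence(self):
        # NG86 ignores the transition/transversion bias, so its omega drifts
        # from the ML value as kappa grows; at kappa = 1.5 the two methods
        # must agree within 15% relative at low divergence
        cfg = EvolSimConfig(tree="(A:0.06,B:0.06);", n_codons=2000, kappa=1.5,
                            site_classes=[(1.0, 0.4)], seed=7)
        aln, _ = simulate_codon_alignment(cfg)
        ml = ml_pairwise_dnds(aln, seed=2)
        ng = ng86_dnds(aln)
        assert ng.ds < 0.2
        assert ml.omega == pytest.approx(ng.omega, rel=0.15)

    def test_identical_sequences_unidentifiable(self):
        aln = CodonAlignment(["a", "b"], ["ATGGCA" * 10, "ATGGCA" * 10])
        with pytest.raises(UnidentifiableError):
            ml_pairwise_dnds(aln)


class TestLRT:
    @pytest.mark.parametrize("stat, df, expected", [
        (0.0, 2, 1.0),
        (5.99, 2, 0.0500),
        (9.21, 2, 0.0100),
        (3.84, 1, 0.0500),
    ])
    def test_chi_square_tail(self, stat, df, expected):
        assert lrt(0.0, stat / 2.0, df) == pytest.approx(expected, abs=2e-4)

    def test_small_negative_statistic_clamped(self):
        assert lrt(-10.0, -10.0 - 1e-9, df=1) == 1.0

    def test_inconsistent_fit_raises(self):
        with pytest.raises(InconsistentFitError):
            lrt(-10.0, -20.0, df=1)


@pytest.fixture(scope="module")
def m1a_data():
    tree = "((A:0.3,B:0.3):0.15,C:0.3,D:0.45);"
    cfg = EvolSimConfig(tree=tree, n_codons=500, kappa=2.0,
                        site_classes=[(0.7, 0.1), (0.3, 1.0)], seed=2)
    aln, labels = simulate_codon_alignment(cfg)
    return tree, aln, labels


class TestSiteModels:
    def test_m2a_likelihood_dominates_m1a(self, m1a_data):
        tree, aln, _ = m1a_data
        f1 = fit_site_model(aln, tree, model="M1a", n_restarts=2, seed=0)
        f2 = fit_site_model(aln, tree, model="M2a", n_restarts=2, seed=0)
        assert f2.lnl >= f1.lnl - 1e-3
        assert abs(sum(f1.class_proportions) - 1.0) < 1e-9
        assert np.allclose(f1.posterior.sum(axis=1), 1.0)

    def test_parameter_recovery_and_neb_classification(self, m1a_data):
        tree, aln, labels = m1a_data
        fit = fit_site_model(aln, tree, model="M1a", n_restarts=2, seed=0)
        assert fit.p0 == pytest.approx(0.7, abs=0.12)
        assert fit.omega0 == pytest.approx(0.1, abs=0.08)
        recall = (fit.site_classes[labels == 0] == 0).mean()
        assert recall >= 0.8

    def test_likelihood_invariant_to_taxon_order(self, m1a_data):
        tree, aln, _ = m1a_data
        perm = [2, 0, 3, 1]
        aln2 = CodonAlignment([aln.taxa[i] for i in perm],
                              [aln.rows[i] for i in perm])
        f1 = fit_site_model(aln, tree, model="M1a", n_restarts=1, seed=0)
        f2 = fit_site_model(aln2, tree, model="M1a", n_restarts=1, seed=0)
        assert f1.lnl == pytest.approx(f2.lnl, abs=0.05)

    def test_too_few_taxa_rejected(self):
        aln = CodonAlignment(["a", "b"], ["ATGGCA", "ATGGCG"])
        with pytest.raises(AlignmentError):
            fit_site_model(aln, "(a:0.1,b:0.1);")


class TestBranchModel:
    def test_uniform_omega_recovered_on_all_branches(self):
        tree = "((A:0.25,B:0.25):0.15,C:0.25,D:0.4);"
        cfg = EvolSimConfig(tree=tree, n_codons=600, kappa=2.0,
                            site_classes=[(1.0, 0.2)], seed=3)
        aln, _ = simulate_codon_alignment(cfg)
        results, kappa, lnl = branch_dnds(aln, tree, seed=0)
        stable = [r for r in results if not r.unstable]
        assert len(stable) >= 3
        for r in stable:
            assert r.omega == pytest.approx(0.2, abs=0.1)

    def test_short_branch_triggers_instability_warning(self, caplog):
        tree = "((A:0.2,B:0.001):0.2,C:0.2,D:0.2);"
        cfg = EvolSimConfig(tree=tree, n_codons=300, kappa=2.0,
                            site_classes=[(1.0, 0.3)], seed=4)
        aln, _ = simulate_codon_alignment(cfg)
        import logging
        with caplog.at_level(logging.WARNING):
            results, _, _ = branch_dnds(aln, tree, n_restarts=1, seed=0)
        assert any(r.unstable for r in results)

    def test_tree_taxa_mismatch_rejected(self):
        aln = CodonAlignment(["a", "b", "c"], ["ATGGCA"] * 3)
        with pytest.raises(AlignmentError):
            branch_dnds(aln, "(a:0.1,b:0.1,x:0.1);")


class TestTajimaRelativeRate:
    def _triplet(self, m1, m2, same=50):
        # build aligned triplet with exactly m1 A-unique and m2 B-unique sites
        a = ["A"] * same + ["C"] * m1 + ["G"] * m2
        b = ["A"] * same + ["A"] * m1 + ["T"] * m2
        o = ["A"] * same + ["A"] * m1 + ["G"] * m2
        return "".join(a), "".join(b), "".join(o)

    def test_balanced_counts_give_p_one(self):
        res = tajima_relative_rate(*self._triplet(10, 10))
        assert res.chi2_stat == 0.0 and res.p_raw == 1.0

    def test_hand_computed_chi_square(self):
        res = tajima_relative_rate(*self._triplet(20, 5))
        assert res.m1 == 20 and res.m2 == 5
        assert res.chi2_stat == pytest.approx(9.0)
        assert res.p_raw == pytest.approx(0.0027, abs=2e-4)

    def test_no_informative_sites_flagged(self):
        res = tajima_relative_rate("AAAA", "AAAA", "AAAA")
        assert res.undefined and res.p_raw == 1.0

    def test_bonferroni_multiplies_and_caps(self):
        r1 = tajima_relative_rate(*self._triplet(20, 5))
        r1.p_raw = 0.004
        r2 = tajima_relative_rate(*self._triplet(20, 5))
        r2.p_raw = 0.5
        bonferroni([r1, r2], n_tests=10)
        assert r1.p_adjusted == pytest.approx(0.04)
        assert r2.p_adjusted == 1.0


class TestModelInternals:
    def test_generator_rows_sum_to_zero_and_stationary_pi(self):
        pi = f3x4_frequencies(["ATGGCATTTCCCGGG" * 4])
        q, _, _ = build_rate_matrix(1.7, 0.4, pi)
        assert np.abs(q.sum(axis=1)).max() < 1e-12
        p = spectral_model(1.7, 0.4, pi).transition_matrix(200.0)
        assert np.abs(p - pi[None, :]).max() < 1e-8

    def test_f3x4_sums_to_one_over_sense_codons(self):
        pi = f3x4_frequencies(["ATGAAATTTCCC"])
        assert pi.sum() == pytest.approx(1.0)
        assert len(pi) == 61

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.floats(0.5, 5.0), st.floats(0.05, 3.0), st.floats(0.01, 2.0))
    def test_chapman_kolmogorov(self, kappa, omega, t):
        pi = uniform_frequencies()
        m = spectral_model(kappa, omega, pi)
        p1 = m.transition_matrix(t)
        p2 = m.transition_matrix(t / 2)
        assert np.allclose(p1, p2 @ p2, atol=1e-10)
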