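"""Closed-form contact probabilities against exact values, each other, and
the Monte-Carlo ensemble oracle."""

from itertools import combinations, permutations

import numpy as np
import pytest
from scipy.integrate import quad

from hlm.contacts import (
    CrosslinkModel,
    conditional_contacts,
    contact_map,
    contact_to_gamma,
    ensemble_contact_probability,
    ensemble_pair_product,
    nbody_contact,
    nbody_contact_from_cov,
    pair_pair_contact,
    pairwise_contact,
    quad_contact,
    triplet_contact,
    triplet_map,
)
from hlm.polymer import (
    PairGeometry,
    build_kirchhoff,
    distance_pdf,
    pair_geometry,
    pinned_covariance,
    sample_ensemble,
)
from hlm.synthetic import make_chain, make_loops

from conftest import assert_close


class TestPairwise:
    def test_gaussian_closed_form_example(self, xl):
        # <r^2> = 3 r_c^2 (gamma = 1/2) -> p = 4^{-3/2} = 0.125
        assert pairwise_contact(PairGeometry(gamma=0.5), xl) == pytest.approx(0.125, abs=1e-15)

    def test_large_capture_radius_limit(self):
        g = PairGeometry(gamma=0.5)
        p = pairwise_contact(g, CrosslinkModel("gaussian", 1e8))
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_step_form_matches_quadrature(self, xl_step):
        # independent oracle: integrate the pair-distance density over [0, r_c]
        g = PairGeometry(gamma=1.0)
        expected, _ = quad(lambda r: distance_pdf(g, r), 0.0, 1.0)
        p = pairwise_contact(g, xl_step)
        assert p == pytest.approx(expected, abs=1e-10)
        assert p == pytest.approx(0.4275933, abs=1e-6)

    def test_monotone_in_capture_radius(self):
        g = PairGeometry(gamma=0.7)
        for form in ("gaussian", "step"):
            ps = [
                pairwise_contact(g, CrosslinkModel(form, rc))
                for rc in (0.5, 1.0, 2.0, 4.0)
            ]
            assert all(a < b for a, b in zip(ps, ps[1:]))

    def test_ensemble_oracle(self, loop_model, loop_ensemble, xl, xl_step):
        _, cov, _ = loop_model
        for (i, j) in [(1, 4), (0, 7), (3, 11)]:
            g = pair_geometry(cov, i, j)
            for form in (xl, xl_step):
                est, se = ensemble_contact_probability(loop_ensemble, (i, j), form)
                assert abs(est - pairwise_contact(g, form)) <= 3 * se


class TestContactToGamma:
    def test_gaussian_inversion_example(self, xl):
        g = contact_to_gamma(0.125, xl)
        assert_close(g.gamma, 0.5, rtol=1e-12)
        assert_close(g.mean_square_distance, 3.0, rtol=1e-12)

    def test_tight_contact_limit(self, xl):
        g = contact_to_gamma(1.0 - 1e-9, xl)
        assert g.mean_square_distance < 1e-6

    @pytest.mark.parametrize("form", ["gaussian", "step"])
    @pytest.mark.parametrize("p", [1e-6, 0.01, 0.3, 0.9, 0.999])
    def test_round_trip(self, form, p):
        x = CrosslinkModel(form, 1.3)
        g = contact_to_gamma(p, x)
        assert pairwise_contact(g, x) == pytest.approx(p, rel=1e-10)

    def test_step_inverse_of_quadrature_value(self, xl_step):
        g = contact_to_gamma(0.42760, xl_step)
        assert g.gamma == pytest.approx(1.0, abs=1e-4)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.2, 1.5])
    def test_domain_errors(self, p, xl):
        with pytest.raises(ValueError):
            contact_to_gamma(p, xl)


class TestTriplet:
    def test_chain_consecutive_example(self, xl):
        cov = pinned_covariance(build_kirchhoff(make_chain(4, 1.0)))
        p = triplet_contact(cov, 0, 1, 2, xl)
        assert_close(p, 40.0**-1.5, rtol=1e-12)

    def test_permutation_invariance(self, loop_model, xl):
        _, cov, _ = loop_model
        vals = {triplet_contact(cov, *perm, xl) for perm in permutations((2, 6, 10))}
        assert max(vals) - min(vals) == 0.0

    def test_duplicate_indices_rejected(self, loop_model, xl):
        _, cov, _ = loop_model
        with pytest.raises(ValueError):
            triplet_contact(cov, 1, 1, 5, xl)

    def test_step_form_needs_ensemble(self, loop_model, xl_step):
        _, cov, _ = loop_model
        with pytest.raises(ValueError, match="ensemble"):
            triplet_contact(cov, 1, 4, 7, xl_step)

    def test_ensemble_oracle(self, loop_model, loop_ensemble, xl):
        _, cov, _ = loop_model
        for t in [(1, 4, 7), (0, 5, 11), (2, 3, 9)]:
            est, se = ensemble_contact_probability(loop_ensemble, t, xl)
            assert abs(est - triplet_contact(cov, *t, xl)) <= 3 * se

    def test_triplet_map_consistency(self, loop_model, xl):
        _, cov, _ = loop_model
        k = 7
        tmap = triplet_map(cov, k, xl)
        assert np.array_equal(tmap, tmap.T)
        assert np.all(tmap > 0) and np.all(tmap <= 1)
        assert tmap[2, 5] == pytest.approx(triplet_contact(cov, 2, 5, k, xl), rel=1e-12)
        # degenerate entries fall back to pairwise
        pmap = contact_map(cov, xl)
        assert tmap[3, k] == pmap[3, k]


class TestQuad:
    def test_chain_consecutive_example(self, xl):
        cov = pinned_covariance(build_kirchhoff(make_chain(5, 1.0)))
        p = quad_contact(cov, 0, 1, 2, 3, xl)
        assert_close(p, 679.0**-1.5, rtol=1e-12)

    def test_large_capture_radius_limit(self, loop_model):
        _, cov, _ = loop_model
        p = quad_contact(cov, 1, 4, 7, 10, CrosslinkModel("gaussian", 1e7))
        assert p == pytest.approx(1.0, abs=1e-10)

    def test_permutation_invariance_vs_general_form(self, loop_model, xl):
        _, cov, _ = loop_model
        sm, _, _ = loop_model
        km = build_kirchhoff(sm)
        ref = nbody_contact(km, (1, 5, 8, 11), xl)
        for perm in permutations((1, 5, 8, 11)):
            assert_close(quad_contact(cov, *perm, xl), ref, rtol=1e-10)

    def test_ensemble_oracle(self, loop_model, loop_ensemble, xl):
        _, cov, _ = loop_model
        for q in [(1, 4, 7, 10), (0, 2, 6, 11)]:
            est, se = ensemble_contact_probability(loop_ensemble, q, xl)
            assert abs(est - quad_contact(cov, *q, xl)) <= 3 * se


class TestNBody:
    def test_two_body_on_two_bead_chain(self, xl):
        km = build_kirchhoff(make_chain(2, 3.0))
        p = nbody_contact(km, (0, 1), xl)
        assert_close(p, 2.0**-1.5, rtol=1e-12)
        g = pair_geometry(pinned_covariance(km), 0, 1)
        assert_close(p, pairwise_contact(g, xl), rtol=1e-12)

    def test_three_body_matches_triplet(self, xl):
        km = build_kirchhoff(make_chain(6, 1.0))
        p = nbody_contact(km, (2, 3, 4), xl)
        assert_close(p, 40.0**-1.5, rtol=1e-12)

    def test_pinned_and_gap_routes_agree(self, sweep_models, xl):
        rng = np.random.default_rng(77)
        for sm, cov in sweep_models:
            km = build_kirchhoff(sm)
            for n_sites in (2, 3, 4, 5, 6):
                sites = tuple(rng.choice(sm.n_bins, n_sites, replace=False))
                a = nbody_contact(km, sites, xl)
                b = nbody_contact_from_cov(cov, sites, xl)
                assert_close(a, b, rtol=1e-9)

    def test_five_body_ensemble_oracle(self):
        # a wider capture radius keeps the 5-body probability large enough
        # for the Monte-Carlo estimate to resolve
        x = CrosslinkModel("gaussian", 2.0)
        sm, _ = make_loops(15, n_loops=4, seed=21)
        km = build_kirchhoff(sm)
        cov = pinned_covariance(km)
        ens = sample_ensemble(cov, 100_000, seed=22)
        sites = (1, 4, 7, 10, 13)
        est, se = ensemble_contact_probability(ens, sites, x)
        assert abs(est - nbody_contact(km, sites, x)) <= 3 * se

    def test_too_few_sites_rejected(self, loop_model, xl):
        sm, cov, _ = loop_model
        with pytest.raises(ValueError):
            nbody_contact(build_kirchhoff(sm), (3,), xl)


class TestPairPairAndConditionals:
    def test_chain_factorizes_when_gaps_uncorrelated(self, xl):
        # ideal chain has b = 0, so the joint two-spring event factorizes
        cov = pinned_covariance(build_kirchhoff(make_chain(4, 1.0)))
        p = pair_pair_contact(cov, 0, 1, 2, xl)
        assert_close(p, 16.0**-1.5, rtol=1e-12)
        assert_close(p, 0.125**2, rtol=1e-12)

    def test_omega_route_agrees_with_closed_form(self, sweep_models, xl):
        for _, cov in sweep_models:
            n = cov.n_bins
            for (i, j, k) in [(0, 2, 5), (1, n // 2, n - 1), (2, 3, 7)]:
                a = pair_pair_contact(cov, i, j, k, xl)
                b = pair_pair_contact(cov, i, j, k, xl, route="omega")
                assert_close(a, b, rtol=1e-10)

    def test_joint_event_dominates_triple_contact(self, loop_model, xl):
        _, cov, _ = loop_model
        for (i, j, k) in combinations(range(cov.n_bins), 3):
            assert pair_pair_contact(cov, i, j, k, xl) >= triplet_contact(
                cov, i, j, k, xl
            )

    def test_ensemble_oracle(self, loop_model, loop_ensemble, xl):
        _, cov, _ = loop_model
        for (i, j, k) in [(1, 4, 7), (0, 6, 11)]:
            est, se = ensemble_pair_product(loop_ensemble, [(i, j), (j, k)], xl)
            assert abs(est - pair_pair_contact(cov, i, j, k, xl)) <= 3 * se

    def test_total_probability_identity(self, loop_model, xl):
        _, cov, _ = loop_model
        for (i, j, k) in combinations(range(cov.n_bins), 3):
            p_ij = pairwise_contact(pair_geometry(cov, i, j), xl)
            p_jk = pairwise_contact(pair_geometry(cov, j, k), xl)
            given, given_not = conditional_contacts(cov, i, j, k, xl)
            assert given * p_ij + given_not * (1 - p_ij) == pytest.approx(
                p_jk, abs=1e-12
            )
            assert given_not <= p_jk <= given

    def test_chain_conditionals_collapse_to_marginal(self, xl):
        # b = 0: conditioning on the i-j contact cannot move p_jk
        cov = pinned_covariance(build_kirchhoff(make_chain(10, 1.0)))
        for (i, j, k) in [(0, 3, 7), (1, 2, 9), (2, 5, 8)]:
            p_jk = pairwise_contact(pair_geometry(cov, j, k), xl)
            given, given_not = conditional_contacts(cov, i, j, k, xl)
            assert given == pytest.approx(p_jk, rel=1e-12)
            assert given_not == pytest.approx(p_jk, rel=1e-12)

    def test_loop_model_strict_cooperativity(self, loop_model, xl):
        # any triple with correlated gaps (b != 0) gives strict inequalities
        from hlm.contacts import triplet_abc

        _, cov, _ = loop_model
        strict = 0
        for (i, j, k) in combinations(range(1, cov.n_bins), 3):
            _, b, _ = triplet_abc(cov, i, j, k)
            if abs(b) < 1e-9:
                continue
            p_jk = pairwise_contact(pair_geometry(cov, j, k), xl)
            given, given_not = conditional_contacts(cov, i, j, k, xl)
            assert given_not < p_jk < given
            strict += 1
        assert strict > 0

    def test_ensemble_conditional_frequencies(self, loop_model, xl):
        # restrict samples by the (soft) i-j cross-link weight and compare
        _, cov, _ = loop_model
        ens = sample_ensemble(cov, 200_000, seed=17)
        i, j, k = 2, 5, 9
        pos = ens.positions
        w_ij = np.asarray(xl(np.linalg.norm(pos[:, i] - pos[:, j], axis=1)))
        w_jk = np.asarray(xl(np.linalg.norm(pos[:, j] - pos[:, k], axis=1)))
        given, given_not = conditional_contacts(cov, i, j, k, xl)
        est_given = (w_ij * w_jk).mean() / w_ij.mean()
        est_not = ((1 - w_ij) * w_jk).mean() / (1 - w_ij).mean()
        # delta-method SE at this sample size is below 1e-3 for both ratios
        assert est_given == pytest.approx(given, abs=3e-3)
        assert est_not == pytest.approx(given_not, abs=3e-3)


class TestMonotonicity:
    def test_every_order_non_decreasing_in_rc(self, loop_model):
        sm, cov, _ = loop_model
        km = build_kirchhoff(sm)
        site_sets = [(0, 5), (1, 4, 7), (2, 5, 8, 11), (0, 3, 6, 9, 11)]
        for sites in site_sets:
            ps = [
                nbody_contact(km, sites, CrosslinkModel("gaussian", rc))
                for rc in (0.5, 1.0, 2.0, 5.0)
            ]
            assert all(a <= b for a, b in zip(ps, ps[1:]))
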