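"""Covariance closed forms against the moving-average quadrature oracle,
and assembly of the full model covariance."""

import numpy as np
import pytest

import streamnet as sn
from streamnet.covariance import (
    CovarianceComponent,
    CovarianceParams,
    assemble_sigma,
    euclid_cov,
    moving_average_oracle,
    taildown_cov,
    tailup_cov,
)
from streamnet.distance import (
    downstream_distance_matrix,
    euclidean_distance_matrix,
    tailup_weights,
)
from streamnet.errors import DimensionError

from conftest import random_network, random_sites


class TestTailup:
    def test_sill_at_zero_distance(self):
        comp = CovarianceComponent("exponential", 2.0, 3.0)
        assert tailup_cov(0.0, 1.0, comp) == pytest.approx(2.0)

    def test_unconnected_is_zero(self):
        comp = CovarianceComponent("exponential", 2.0, 3.0)
        assert tailup_cov(5.0, 0.0, comp) == 0.0

    def test_exponential_value(self):
        comp = CovarianceComponent("exponential", 1.0, 10.0)
        assert tailup_cov(5.0, 0.5, comp) == pytest.approx(0.5 * np.exp(-0.5))

    def test_negative_distance_rejected(self):
        comp = CovarianceComponent("exponential", 1.0, 1.0)
        with pytest.raises(ValueError):
            tailup_cov(-1.0, 1.0, comp)


class TestTaildown:
    def test_sill_at_zero(self):
        comp = CovarianceComponent("spherical", 3.0, 2.0)
        assert taildown_cov(True, 0.0, 0.0, 0.0, comp) == pytest.approx(3.0)

    def test_exponential_unconnected_factorizes(self):
        comp = CovarianceComponent("exponential", 1.0, 4.0)
        v = taildown_cov(False, 4.0, 3.0, 1.0, comp)
        assert v == pytest.approx(np.exp(-1.0))
        assert v == pytest.approx(np.exp(-3 / 4) * np.exp(-1 / 4))

    def test_spherical_fu_with_b_zero_reduces_to_fc(self):
        # (1-t)^2 (1+t/2) = 1 - (3/2) t + (1/2) t^3
        comp = CovarianceComponent("spherical", 1.0, 5.0)
        for a in [0.0, 1.0, 2.5, 4.9]:
            fu = taildown_cov(False, a, a, 0.0, comp)
            fc = taildown_cov(True, a, a, 0.0, comp)
            assert fu == pytest.approx(fc, abs=1e-14)

    def test_b_greater_than_a_rejected(self):
        comp = CovarianceComponent("exponential", 1.0, 1.0)
        with pytest.raises(ValueError):
            taildown_cov(False, 3.0, 1.0, 2.0, comp)


class TestEuclid:
    def test_forms(self):
        assert euclid_cov(0.0, CovarianceComponent("gaussian", 2.0, 1.0)) == 2.0
        assert euclid_cov(3.0, CovarianceComponent("gaussian", 1.0, 3.0)) == (
            pytest.approx(np.exp(-1.0))
        )
        assert euclid_cov(5.0, CovarianceComponent("spherical", 1.0, 5.0)) == 0.0
        assert euclid_cov(7.0, CovarianceComponent("spherical", 1.0, 5.0)) == 0.0
        assert euclid_cov(2.0, CovarianceComponent("exponential", 1.0, 2.0)) == (
            pytest.approx(np.exp(-1.0))
        )


class TestMovingAverageOracle:
    def test_normalization(self):
        for k in ("exponential", "linear_sill", "spherical"):
            assert moving_average_oracle(k, 0.0, 0.0, 2.0) == pytest.approx(1.0)

    def test_spherical_half_range(self):
        assert moving_average_oracle("spherical", 0.5, 0.0, 1.0) == pytest.approx(
            0.3125, abs=1e-9
        )

    def test_exponential_analytic(self):
        assert moving_average_oracle("exponential", 1.2, 0.7, 2.0) == pytest.approx(
            np.exp(-(1.2 + 0.7) / 2.0), abs=1e-9
        )

    @pytest.mark.parametrize("kind", ["exponential", "linear_sill", "spherical"])
    def test_closed_forms_match_oracle(self, kind):
        """Spot grid; the full 200-point sweep runs in the acceptance suite."""
        comp = CovarianceComponent(kind, 1.0, 1.0)
        for ta in [0.0, 0.3, 0.8, 1.5]:
            for tb in [0.0, 0.2, 0.8]:
                if tb > ta:
                    continue
                want = moving_average_oracle(kind, ta, tb, 1.0)
                got_fu = taildown_cov(False, ta + tb, ta, tb, comp)
                assert got_fu == pytest.approx(want, abs=1e-6)
            want_fc = moving_average_oracle(kind, ta, 0.0, 1.0)
            got_fc = taildown_cov(True, ta, ta, 0.0, comp)
            assert got_fc == pytest.approx(want_fc, abs=1e-6)
            got_tu = tailup_cov(ta, 1.0, comp)
            assert got_tu == pytest.approx(want_fc, abs=1e-6)


class TestAssembleSigma:
    def _pieces(self, seed=0, n=20):
        net = random_network(seed, n_edges=40)
        sites = random_sites(net, n, seed=seed + 1)
        d = downstream_distance_matrix(sites, sites, net)
        W = tailup_weights(sites, sites, net, d)
        de = euclidean_distance_matrix(sites, sites)
        return net, sites, d, W, de

    def test_iid_model(self):
        _, _, d, W, de = self._pieces()
        params = CovarianceParams(nugget=1.7)
        sigma = assemble_sigma(d, W, de, params, True)
        assert np.allclose(sigma, 1.7 * np.eye(len(de)))

    def test_sum_of_components(self, reference_params):
        _, _, d, W, de = self._pieces()
        total = assemble_sigma(d, W, de, reference_params, True)
        manual = (
            tailup_cov(d.h, W, reference_params.tailup)
            + taildown_cov(d.flow_connected, d.h, d.a, d.b, reference_params.taildown)
            + euclid_cov(de, reference_params.euclid)
            + reference_params.nugget * np.eye(len(de))
        )
        assert np.allclose(total, manual, atol=1e-14)

    def test_diagonal_is_total_variance(self, reference_params):
        _, _, d, W, de = self._pieces()
        sigma = assemble_sigma(d, W, de, reference_params, True)
        assert np.allclose(np.diag(sigma), reference_params.total_variance)
        assert reference_params.total_variance == pytest.approx(2 + 2 + 1 + 0.5)

    def test_cross_network_pairs_keep_euclid_only(self, reference_params):
        net = sn.build_network(
            [
                {"edge_id": 1, "down_edge_id": None, "length": 5, "additive_attr": 1,
                 "net_id": 1},
                {"edge_id": 2, "down_edge_id": None, "length": 5, "additive_attr": 1,
                 "net_id": 2},
            ]
        )
        sn.compute_afv(net)
        sites = sn.locate_sites(
            [
                {"site_id": 1, "edge_id": 1, "ratio": 0.5, "x": 0.0, "y": 0.0},
                {"site_id": 2, "edge_id": 2, "ratio": 0.5, "x": 3.0, "y": 4.0},
            ],
            net,
        )
        d = downstream_distance_matrix(sites, sites, net)
        W = tailup_weights(sites, sites, net, d)
        de = euclidean_distance_matrix(sites, sites)
        sigma = assemble_sigma(d, W, de, reference_params, True)
        expected = euclid_cov(5.0, reference_params.euclid)
        assert sigma[0, 1] == pytest.approx(float(expected))
        assert sigma[0, 1] > 0

    def test_dimension_mismatch(self, reference_params):
        _, _, d, W, de = self._pieces()
        with pytest.raises(DimensionError):
            assemble_sigma(d, W[:-1], de, reference_params, True)

    @pytest.mark.parametrize("seed", range(6))
    def test_positive_definite_after_nugget(self, seed, reference_params):
        _, _, d, W, de = self._pieces(seed=seed, n=25)
        no_nug = CovarianceParams(
            tailup=reference_params.tailup,
            taildown=reference_params.taildown,
            euclid=reference_params.euclid,
            nugget=0.0,
        )
        base = assemble_sigma(d, W, de, no_nug, True)
        ev = np.linalg.eigvalsh(base)
        assert ev.min() >= -1e-8 * ev.max()
        with_nug = assemble_sigma(d, W, de, reference_params, True)
        assert np.linalg.eigvalsh(with_nug).min() > 0

    def test_monotone_in_distance(self):
        # flow-connected correlations never increase with h; flow-unconnected
        # exponential never increases in a+b at fixed a-b
        for kind in ("exponential", "spherical", "linear_sill"):
            comp = CovarianceComponent(kind, 1.0, 2.0)
            h = np.linspace(0, 5, 60)
            v = taildown_cov(np.ones_like(h, bool), h, h, np.zeros_like(h), comp)
            assert np.all(np.diff(v) <= 1e-12)
        comp = CovarianceComponent("exponential", 1.0, 2.0)
        gap = 0.5
        s = np.linspace(gap, 4, 40)  # a+b = 2s varying, a-b = gap fixed
        a = (2 * s + gap) / 2
        b = (2 * s - gap) / 2
        v = taildown_cov(np.zeros_like(s, bool), a + b, a, b, comp)
        assert np.all(np.diff(v) <= 1e-12)
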