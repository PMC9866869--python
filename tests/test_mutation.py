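"""Stationary grids, flux-parameterized UNREST generators, uniformization,
and the codon tensor lift."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import null_space

import fourfold as ff
from fourfold.mutation import NegativeFluxError, ZeroGeneratorError, repair_params
from tests.conftest import random_grid_pressure


def brute_force_grid(lo_n, hi_n, denom):
    """Independent enumeration oracle over integer step counts."""
    pts = []
    for tup in itertools.product(range(lo_n, hi_n + 1), repeat=4):
        if sum(tup) == denom:
            pts.append(tup)
    return pts


class TestGridEnumeration:
    def test_default_grid_size(self):
        # closed form: a+b+c+d=100, 5 <= each <= 85  ->  C(83, 3) = 91,881
        grid = ff.enumerate_stationary_grid()
        assert len(grid) == 91881

    def test_tabulated_extreme_pressure_is_on_the_grid(self):
        target = ff.StationaryDistribution.from_atcg(0.84, 0.05, 0.05, 0.06)
        grid = ff.enumerate_stationary_grid()
        assert target in set(grid)

    def test_tuples_sum_to_one_on_the_integer_lattice(self):
        for pi in ff.enumerate_stationary_grid(0.1, 0.7, 0.1):
            counts = [round(f * 10) for f in pi.as_array()]
            assert sum(counts) == 10

    @given(
        lo_n=st.integers(1, 4),
        hi_n=st.integers(5, 9),
        denom=st.sampled_from([10, 20]),
    )
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force_enumeration(self, lo_n, hi_n, denom):
        expected = brute_force_grid(lo_n, hi_n, denom)
        try:
            grid = ff.enumerate_stationary_grid(
                lo_n / denom, hi_n / denom, 1 / denom
            )
        except ff.EmptyGridError:
            assert not expected
            return
        got = {
            tuple(round(f * denom) for f in pi.as_array()) for pi in grid
        }
        assert got == set(expected)
        assert len(grid) == len(expected)  # no duplicates

    def test_empty_grid_is_an_error(self):
        with pytest.raises(ff.EmptyGridError):
            ff.enumerate_stationary_grid(0.3, 0.4, 0.01)


class TestFluxToRates:
    def test_zero_circulation_gives_detailed_balance(self):
        pi = ff.StationaryDistribution.from_atcg(0.4, 0.3, 0.2, 0.1)
        q = ff.flux_to_rates([0.2, 0.1, 0.3, 0.15, 0.05, 0.2], [0, 0, 0], pi)
        pvec = pi.as_array()
        flux = pvec[:, None] * q.q
        assert np.allclose(flux, flux.T, atol=1e-14)

    def test_uniform_pi_equal_symmetric_fluxes_give_equal_rates(self):
        pi = ff.StationaryDistribution([0.25] * 4)
        q = ff.flux_to_rates([1.0] * 6, [0, 0, 0], pi)
        off = q.q[~np.eye(4, dtype=bool)]
        assert np.allclose(off, off[0])

    def test_excess_circulation_is_rejected(self):
        pi = ff.StationaryDistribution([0.25] * 4)
        with pytest.raises(NegativeFluxError):
            ff.flux_to_rates([0.01] * 6, [1.0, 0, 0], pi)

    def test_zero_parameters_are_rejected(self):
        pi = ff.StationaryDistribution([0.25] * 4)
        with pytest.raises(ZeroGeneratorError):
            ff.flux_to_rates([0.0] * 6, [0, 0, 0], pi)

    def test_scale_normalization(self):
        rng = np.random.default_rng(5)
        pi = random_grid_pressure(rng)
        q = ff.sample_rate_matrix(pi, 11)
        assert float(-(pi.as_array() * np.diag(q.q)).sum()) == pytest.approx(1.0)

    def test_flux_parameterization_recovers_arbitrary_unrest(self):
        """Surjectivity spot check: a stationarity-constrained UNREST matrix
        built independently is reproduced by fitting fluxes."""
        rng = np.random.default_rng(17)
        for _ in range(10):
            pi = random_grid_pressure(rng)
            q0 = ff.sample_rate_matrix(pi, int(rng.integers(2**31))).q
            flux = pi.as_array()[:, None] * q0
            np.fill_diagonal(flux, 0.0)
            sym = [(flux[i, j] + flux[j, i]) / 2 for i, j in ff.mutation.NUCLEOTIDE_PAIRS]
            anti = (flux - flux.T) / 2
            # circulation coordinates on the K4 cycle basis read off the
            # non-tree edges C-G, C-T, G-T
            circ = [anti[1, 2], anti[1, 3], anti[2, 3]]
            q1 = ff.flux_to_rates(sym, circ, pi)
            assert np.allclose(q1.q, q0, atol=1e-8)


class TestSampleRateMatrix:
    def test_stationarity_against_null_space_oracle(self):
        rng = np.random.default_rng(1234)
        for k in range(100):
            pi = random_grid_pressure(rng)
            q = ff.sample_rate_matrix(pi, k)
            assert q.stationarity_residual() < 1e-10
            ns = null_space(q.q.T)
            assert ns.shape[1] == 1
            recovered = ns[:, 0] / ns[:, 0].sum()
            assert np.abs(recovered - pi.as_array()).max() < 1e-8

    def test_different_seeds_differ(self):
        pi = ff.StationaryDistribution([0.25] * 4)
        q1 = ff.sample_rate_matrix(pi, 1)
        q2 = ff.sample_rate_matrix(pi, 2)
        assert not np.allclose(q1.q, q2.q)


class TestUniformize:
    def test_max_exit_row_has_zero_diagonal(self):
        rng = np.random.default_rng(3)
        pi = random_grid_pressure(rng)
        q = ff.sample_rate_matrix(pi, 9)
        p = ff.uniformize(q)
        row = int(np.argmax(np.abs(np.diag(q.q))))
        assert p.p[row, row] == pytest.approx(0.0, abs=1e-15)
        assert np.allclose(p.p.sum(axis=1), 1.0, atol=1e-12)

    def test_stationarity_preserved(self):
        rng = np.random.default_rng(4)
        for k in range(20):
            pi = random_grid_pressure(rng)
            p = ff.uniformize(ff.sample_rate_matrix(pi, k))
            assert np.abs(pi.as_array() @ p.p - pi.as_array()).max() < 1e-12

    def test_powers_converge_to_stationary(self):
        pi = ff.StationaryDistribution.from_atcg(0.4, 0.2, 0.25, 0.15)
        p = ff.uniformize(ff.sample_rate_matrix(pi, 21)).p
        for _ in range(10):  # P^(2^10)
            p = p @ p
        assert np.abs(p - pi.as_array()[None, :]).max() < 1e-8

    def test_sub_unit_multiplier_rejected(self):
        pi = ff.StationaryDistribution([0.25] * 4)
        q = ff.sample_rate_matrix(pi, 0)
        with pytest.raises(ValueError):
            ff.uniformize(q, lam_multiplier=0.5)


class TestCodonLift:
    def test_identity_lifts_to_identity(self):
        p = ff.NucleotideTransitionMatrix(
            p=np.eye(4), lam=1.0, pi=ff.StationaryDistribution([0.25] * 4)
        )
        m = ff.codon_mutation_matrix(p)
        assert np.array_equal(m.m, np.eye(64))

    def test_entries_are_positional_products(self):
        rng = np.random.default_rng(8)
        pi = random_grid_pressure(rng)
        p = ff.uniformize(ff.sample_rate_matrix(pi, 30))
        m = ff.codon_mutation_matrix(p)
        i, j = ff.CODON_INDEX["GCA"], ff.CODON_INDEX["GCC"]
        n = ff.NUCLEOTIDES.index
        expected = p.p[n("G"), n("G")] * p.p[n("C"), n("C")] * p.p[n("A"), n("C")]
        assert m.m[i, j] == pytest.approx(expected, rel=1e-14)

    def test_stationary_is_outer_product_eigen_oracle(self):
        rng = np.random.default_rng(12)
        pi = random_grid_pressure(rng)
        p = ff.uniformize(ff.sample_rate_matrix(pi, 44))
        m = ff.codon_mutation_matrix(p)
        vals, vecs = np.linalg.eig(m.m.T)
        k = int(np.argmin(np.abs(vals - 1.0)))
        lead = np.real(vecs[:, k])
        lead /= lead.sum()
        pv = pi.as_array()
        analytic = np.kron(np.kron(pv, pv), pv)
        assert np.abs(lead - analytic).max() < 1e-10

    def test_third_position_marginal_equals_pi(self):
        rng = np.random.default_rng(13)
        pi = random_grid_pressure(rng)
        p = ff.uniformize(ff.sample_rate_matrix(pi, 45))
        m = ff.codon_mutation_matrix(p)
        stat = ff.stationary_distribution(m)
        marginal = stat.freq.reshape(16, 4).sum(axis=0)
        assert np.abs(marginal - pi.as_array()).max() < 1e-10


def test_repair_projects_into_feasible_region():
    rng = np.random.default_rng(99)
    for _ in range(50):
        raw = rng.normal(size=9)
        p = repair_params(raw)
        assert p[:6].min() >= 0.0
        if p[:6].sum() > 0:
            fp = ff.FluxParams.from_array(p)
            ff.flux_to_rates(fp.sym, fp.circ, ff.StationaryDistribution([0.25] * 4))
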