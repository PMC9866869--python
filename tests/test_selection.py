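"""Grantham acceptance, the combined chain, and its stationary distribution."""

import numpy as np
import pytest

import fourfold as ff
from fourfold.selection import MultipleRecurrentClassesError
from tests.conftest import combined_chain, random_grid_pressure


class TestGrantham:
    def test_zero_diagonal_and_symmetry(self):
        d = ff.grantham_matrix()
        assert np.array_equal(d, d.T)
        assert np.all(np.diag(d) == 0)

    @pytest.mark.parametrize(
        "x,y,dist",
        [("Leu", "Ile", 5), ("Cys", "Trp", 215), ("Asp", "Glu", 45),
         ("Phe", "Tyr", 22), ("S", "R", 110)],
    )
    def test_reference_distances(self, x, y, dist):
        assert ff.grantham_distance(x, y) == dist
        assert ff.grantham_distance(y, x) == dist

    def test_maximum_is_cys_trp(self):
        assert ff.grantham_matrix().max() == 215

    def test_unknown_residue(self):
        with pytest.raises(KeyError, match="Xyz"):
            ff.grantham_distance("Xyz", "Ala")


class TestAcceptanceMatrix:
    def test_unit_diagonal_and_extreme_pair(self, grantham_acceptance):
        a = grantham_acceptance
        assert np.allclose(np.diag(a.a), 1.0)
        assert a.of("Cys", "Trp") == pytest.approx(0.0)
        assert a.of("Leu", "Ile") == pytest.approx(1 - 5 / 215)

    def test_symmetry(self, grantham_acceptance):
        assert np.array_equal(grantham_acceptance.a, grantham_acceptance.a.T)

    def test_stop_entries_take_the_floor(self):
        acc = ff.build_acceptance_matrix(stop_floor=0.0)
        assert acc.of("Gly", "Stop") == 0.0
        assert acc.of("Stop", "Gly") == 0.0
        assert acc.of("Stop", "Stop") == 1.0

    def test_strict_floor_validation(self):
        # the linear conversion reaches 0 (Cys-Trp), so any positive floor
        # violates the "least accepted" precondition under strict mode
        with pytest.raises(ValueError, match="strict"):
            ff.build_acceptance_matrix(stop_floor=0.5)
        acc = ff.build_acceptance_matrix(stop_floor=0.5, strict=False)
        assert acc.of("Ala", "Stop") == 0.5

    def test_floor_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            ff.build_acceptance_matrix(stop_floor=-0.1, strict=False)
        with pytest.raises(ValueError):
            ff.build_acceptance_matrix(stop_floor=1.5, strict=False)

    def test_conversion_hook(self):
        acc = ff.build_acceptance_matrix(
            conversion=lambda d: np.exp(-d / 100.0)
        )
        assert acc.of("Cys", "Trp") == pytest.approx(np.exp(-2.15))


class TestCombinedChain:
    def test_neutral_acceptance_is_identity_filter(self, sgc, neutral_acceptance):
        rng = np.random.default_rng(7)
        pi = random_grid_pressure(rng)
        p = ff.uniformize(ff.sample_rate_matrix(pi, 3))
        m = ff.codon_mutation_matrix(p)
        ms = ff.combined_codon_matrix(m, neutral_acceptance, sgc)
        assert np.allclose(ms.m, m.m, atol=1e-15)

    def test_stop_gain_is_blocked_at_zero_floor(self, sgc, grantham_acceptance):
        rng = np.random.default_rng(8)
        pi = random_grid_pressure(rng)
        _, ms = combined_chain(sgc, pi, grantham_acceptance, 4)
        assert ms.m[ff.CODON_INDEX["GGA"], ff.CODON_INDEX["TGA"]] == 0.0

    def test_rows_sum_to_one(self, sgc, grantham_acceptance):
        rng = np.random.default_rng(9)
        pi = random_grid_pressure(rng)
        _, ms = combined_chain(sgc, pi, grantham_acceptance, 5)
        assert np.allclose(ms.m.sum(axis=1), 1.0, atol=1e-12)


class TestStationary:
    def test_doubly_stochastic_gives_uniform(self):
        m = ff.CodonTransitionMatrix(m=np.full((64, 64), 1 / 64))
        stat = ff.stationary_distribution(m)
        assert np.allclose(stat.freq, 1 / 64, atol=1e-14)

    def test_matches_power_iteration_on_combined_chains(
        self, sgc, grantham_acceptance
    ):
        rng = np.random.default_rng(10)
        for k in range(10):
            pi = random_grid_pressure(rng)
            _, ms = combined_chain(sgc, pi, grantham_acceptance, 100 + k)
            stat = ff.combined_stationary(ms, sgc)
            power = ms.m.copy()
            for _ in range(20):  # M^(2^20)
                power = power @ power
                power /= power.sum(axis=1, keepdims=True)
            sense = list(sgc.sense_indices)
            assert np.abs(power[sense[0]] - stat.freq).max() < 1e-10

    def test_zero_floor_leaves_stops_empty(self, grantham_acceptance):
        rng = np.random.default_rng(11)
        for cid in ff.registered_ids():
            code = ff.get_code(cid)
            pi = random_grid_pressure(rng)
            _, ms = combined_chain(code, pi, grantham_acceptance, 200 + cid)
            stat = ff.combined_stationary(ms, code)
            stops = list(code.stop_indices)
            assert stat.freq[stops].sum() == 0.0 if stops else True
            assert stat.freq.sum() == pytest.approx(1.0, abs=1e-10)

    def test_full_chain_with_isolated_stops_raises(self, sgc, grantham_acceptance):
        rng = np.random.default_rng(12)
        pi = random_grid_pressure(rng)
        _, ms = combined_chain(sgc, pi, grantham_acceptance, 300)
        with pytest.raises(MultipleRecurrentClassesError):
            ff.stationary_distribution(ms)

    def test_continuity_in_stop_floor(self, sgc):
        """Group-relative usage at floor 0 and at a tiny positive floor agree,
        guarding the sense-class restriction against the ergodicity trick."""
        rng = np.random.default_rng(13)
        pi = random_grid_pressure(rng)
        rels = []
        for floor in (0.0, 1e-9):
            acc = ff.build_acceptance_matrix(stop_floor=floor, strict=False)
            _, ms = combined_chain(sgc, pi, acc, 400)
            stat = ff.combined_stationary(ms, sgc)
            group = [ff.CODON_INDEX["GG" + n] for n in ff.NUCLEOTIDES]
            rels.append(stat.freq[group] / stat.freq[group].sum())
        assert np.abs(rels[0] - rels[1]).max() < 1e-6

    def test_neutral_selection_factorizes(self, sgc, neutral_acceptance):
        rng = np.random.default_rng(14)
        pi = random_grid_pressure(rng)
        _, ms = combined_chain(sgc, pi, neutral_acceptance, 500)
        stat = ff.combined_stationary(ms, sgc)
        pv = pi.as_array()
        assert np.abs(stat.freq - np.kron(np.kron(pv, pv), pv)).max() < 1e-9
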