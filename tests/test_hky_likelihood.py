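"""HKY transition matrices, the star-tree likelihood, and the two ML fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm

from promselnet.alignment import TripletAlignment
from promselnet.hky import (
    BranchLengths,
    HKYParams,
    PromoterScales,
    _rate_matrix,
    hky_matrix,
)
from promselnet.likelihood import (
    alignment_loglik,
    empirical_base_freqs,
    fit_neutral,
    fit_scales,
)
from promselnet.simulate import simulate_triplet

JC = HKYParams(kappa=1.0, pi=(0.25, 0.25, 0.25, 0.25))
BASES = "ACGT"


def triplet(h, c, m):
    return TripletAlignment(("human", "chimp", "macaque"), (h, c, m))


def brute_force_loglik(aln, hky, bl, scales):
    """Independent oracle: expm matrices + explicit loop over internal states."""
    Q = _rate_matrix(hky)
    Ph = expm(Q * scales.zeta_h * bl.t_h)
    Pc = expm(Q * scales.zeta_c * bl.t_c)
    Pm = expm(Q * scales.zeta_m * bl.t_m)
    pi = hky.pi_array
    code = {b: i for i, b in enumerate(BASES)}
    total = 0.0
    for h, c, m in zip(*aln.seqs):
        if any(ch not in BASES for ch in (h, c, m)):
            continue
        p = sum(
            pi[x] * Ph[x, code[h]] * Pc[x, code[c]] * Pm[x, code[m]] for x in range(4)
        )
        total += np.log(p)
    return total


params_strategy = st.builds(
    lambda k, a, b, c: HKYParams(
        kappa=k,
        pi=tuple(np.array([a, b, c, 1.0]) / (a + b + c + 1.0)),
    ),
    st.floats(0.2, 20.0),
    st.floats(0.2, 3.0),
    st.floats(0.2, 3.0),
    st.floats(0.2, 3.0),
)


class TestHKYMatrix:
    def test_zero_branch_is_identity(self):
        np.testing.assert_allclose(hky_matrix(JC, 0.0), np.eye(4), atol=1e-14)

    def test_jukes_cantor_closed_form(self):
        t = 0.1
        P = hky_matrix(JC, t)
        diag = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
        off = 0.25 - 0.25 * np.exp(-4.0 * t / 3.0)
        expected = np.full((4, 4), off)
        np.fill_diagonal(expected, diag)
        np.testing.assert_allclose(P, expected, atol=1e-12)

    def test_long_branch_reaches_stationarity(self):
        params = HKYParams(kappa=5.0, pi=(0.4, 0.1, 0.2, 0.3))
        P = hky_matrix(params, 500.0)
        np.testing.assert_allclose(P, np.tile(params.pi_array, (4, 1)), atol=1e-9)

    def test_negative_branch_rejected(self):
        with pytest.raises(ValueError):
            hky_matrix(JC, -0.1)

    @given(params_strategy, st.floats(0.0, 5.0))
    @settings(max_examples=100, deadline=None)
    def test_row_stochastic_and_detailed_balance(self, params, t):
        P = hky_matrix(params, t)
        np.testing.assert_allclose(P.sum(axis=1), np.ones(4), atol=1e-12)
        pi = params.pi_array
        np.testing.assert_allclose(pi[:, None] * P, (pi[:, None] * P).T, atol=1e-10)

    @given(params_strategy, st.floats(0.001, 2.0))
    @settings(max_examples=50, deadline=None)
    def test_matches_matrix_exponential(self, params, t):
        np.testing.assert_allclose(
            hky_matrix(params, t), expm(_rate_matrix(params) * t), atol=1e-11
        )

    def test_mean_rate_is_one(self):
        params = HKYParams(kappa=7.0, pi=(0.35, 0.15, 0.15, 0.35))
        Q = _rate_matrix(params)
        assert -float(params.pi_array @ np.diag(Q)) == pytest.approx(1.0, abs=1e-12)


class TestAlignmentLoglik:
    def test_single_identical_column_zero_branches(self):
        ll = alignment_loglik(triplet("A", "A", "A"), JC, BranchLengths(0, 0, 0))
        assert ll == pytest.approx(np.log(0.25))

    def test_impossible_column_zero_branches(self):
        ll = alignment_loglik(triplet("A", "C", "A"), JC, BranchLengths(0, 0, 0))
        assert ll == -np.inf

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(7)
        hky = HKYParams(kappa=3.0, pi=(0.3, 0.2, 0.2, 0.3))
        bl = BranchLengths(0.01, 0.02, 0.05)
        scales = PromoterScales(2.5, 0.7, 1.1)
        for _ in range(20):
            seqs = tuple(
                "".join(rng.choice(list(BASES), size=5)) for _ in range(3)
            )
            aln = TripletAlignment(("h", "c", "m"), seqs)
            assert alignment_loglik(aln, hky, bl, scales) == pytest.approx(
                brute_force_loglik(aln, hky, bl, scales), abs=1e-10
            )

    def test_column_order_invariance_and_doubling(self):
        hky = HKYParams(kappa=2.0, pi=(0.25, 0.25, 0.25, 0.25))
        bl = BranchLengths(0.05, 0.05, 0.1)
        aln = triplet("ACGTT", "ACGTA", "ACCTT")
        perm = triplet("TACGT", "AACGT", "TACCT")  # same multiset of columns
        ll = alignment_loglik(aln, hky, bl)
        assert alignment_loglik(perm, hky, bl) == pytest.approx(ll, abs=1e-10)
        doubled = triplet("ACGTT" * 2, "ACGTA" * 2, "ACCTT" * 2)
        assert alignment_loglik(doubled, hky, bl) == pytest.approx(2 * ll, abs=1e-9)

    def test_gap_and_n_columns_dropped(self):
        hky = HKYParams(kappa=2.0, pi=(0.25, 0.25, 0.25, 0.25))
        bl = BranchLengths(0.05, 0.05, 0.1)
        base = triplet("ACG", "ACG", "ACG")
        padded = triplet("ACG-N", "ACGAA", "ACGAA")
        assert alignment_loglik(padded, hky, bl) == pytest.approx(
            alignment_loglik(base, hky, bl)
        )


class TestFitNeutral:
    def test_identical_sequences_drive_branches_to_zero(self):
        s = "ACGT" * 500
        fit = fit_neutral(triplet(s, s, s), n_restarts=2)
        assert fit.branch_lengths.t_h < 1e-4
        assert fit.branch_lengths.t_c < 1e-4
        assert fit.branch_lengths.t_m < 1e-4

    def test_parameter_recovery_moderate_size(self):
        hky = HKYParams(kappa=4.0, pi=(0.3, 0.2, 0.2, 0.3))
        bl = BranchLengths(0.005, 0.005, 0.03)
        aln = simulate_triplet(hky, bl, PromoterScales(), 40000, seed=11, role="intron")
        fit = fit_neutral(aln, n_restarts=3)
        assert fit.hky.kappa == pytest.approx(4.0, rel=0.25)
        assert fit.branch_lengths.t_m == pytest.approx(0.03, rel=0.2)
        assert fit.branch_lengths.t_h + fit.branch_lengths.t_c == pytest.approx(
            0.01, rel=0.3
        )

    def test_local_optimality(self):
        hky = HKYParams(kappa=4.0, pi=(0.3, 0.2, 0.2, 0.3))
        bl = BranchLengths(0.005, 0.005, 0.03)
        aln = simulate_triplet(hky, bl, PromoterScales(), 5000, seed=3, role="intron")
        fit = fit_neutral(aln, n_restarts=3)
        rng = np.random.default_rng(0)
        theta = np.array(
            [fit.hky.kappa, fit.branch_lengths.t_h, fit.branch_lengths.t_c, fit.branch_lengths.t_m]
        )
        for _ in range(40):
            probe = theta * rng.uniform(0.9, 1.1, size=4)
            ll = alignment_loglik(
                aln,
                HKYParams(kappa=float(probe[0]), pi=fit.hky.pi),
                BranchLengths(*probe[1:]),
            )
            assert ll <= fit.lnL + 1e-6

    def test_empirical_frequencies_used(self):
        aln = simulate_triplet(
            HKYParams(kappa=4.0, pi=(0.4, 0.1, 0.1, 0.4)),
            BranchLengths(0.01, 0.01, 0.03),
            PromoterScales(),
            20000,
            seed=5,
        )
        freqs = empirical_base_freqs(aln)
        assert freqs[0] + freqs[3] == pytest.approx(0.8, abs=0.02)
        fit = fit_neutral(aln, n_restarts=2)
        np.testing.assert_allclose(fit.hky.pi_array, freqs, atol=1e-12)


@pytest.fixture(scope="module")
def neutral():
    hky = HKYParams(kappa=4.0, pi=(0.3, 0.2, 0.2, 0.3))
    bl = BranchLengths(0.005, 0.005, 0.03)
    return hky, bl


class TestFitScales:

    def test_recovery_of_unit_scales_long_alignment(self, neutral):
        hky, bl = neutral
        prom = simulate_triplet(hky, bl, PromoterScales(1, 1, 1), 50000, seed=21)
        scales, _ = fit_scales(prom, hky, bl, n_restarts=3)
        assert scales.zeta_h == pytest.approx(1.0, abs=0.3)
        assert scales.zeta_c == pytest.approx(1.0, abs=0.3)
        assert scales.zeta_m == pytest.approx(1.0, abs=0.15)

    def test_interior_null_equals_unconstrained(self, neutral):
        hky, bl = neutral
        # simulate decelerated human branch so the unconstrained MLE is < 1
        prom = simulate_triplet(hky, bl, PromoterScales(0.2, 1, 1), 30000, seed=22)
        free, ll_free = fit_scales(prom, hky, bl, constrain_human=False, n_restarts=3)
        assert free.zeta_h < 1.0
        clamped, ll_null = fit_scales(
            prom, hky, bl, constrain_human=True, n_restarts=3,
            extra_starts=[free.as_array()],
        )
        assert ll_null == pytest.approx(ll_free, abs=1e-6)

    def test_accelerated_human_branch_detected(self, neutral):
        hky, bl = neutral
        hits = 0
        for seed in range(10):
            prom = simulate_triplet(hky, bl, PromoterScales(5, 1, 1), 1000, seed=seed)
            scales, _ = fit_scales(prom, hky, bl, n_restarts=2)
            hits += scales.zeta_h > 1.0
        assert hits >= 8
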