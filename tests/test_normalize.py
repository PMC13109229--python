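"""Normalized syntax measures sigma_C and sigma_J."""

import numpy as np
import pytest

from microsyntax import (
    DomainError,
    MicrostateSequence,
    normalized_profile,
    sigma_continuous,
    sigma_jump,
    syntax_profile,
)
from microsyntax.surrogates import sample_chain
from microsyntax.synthetic import (
    GeneratorConfig,
    generate_chain,
    random_jump_matrix,
    second_order_jump_table,
)


class TestSigmaScalars:
    def test_fixed_point_zero_order(self):
        assert sigma_continuous(2.0, 2.0, 1.0) == 0.0

    def test_fixed_point_first_order_both_variants(self):
        assert sigma_continuous(1.0, 2.0, 1.0) == 1.0
        assert sigma_jump(1.0, 1.0) == 1.0

    def test_direct_evaluations(self):
        assert sigma_continuous(0.5, 2.0, 1.0) == pytest.approx(2.0)
        assert sigma_jump(0.5, 1.0) == pytest.approx(2.0)

    def test_continuity_just_below_baseline(self):
        assert sigma_jump(0.999, 1.0) == pytest.approx(1.0, abs=0.01)
        assert sigma_jump(0.999, 1.0) > 1.0

    def test_strictly_decreasing_in_h(self):
        hs = np.linspace(0.1, 2.0, 25)
        vc = [sigma_continuous(h, 2.0, 1.0) for h in hs]
        vj = [sigma_jump(h, 1.0) for h in hs[hs <= 1.0]]
        assert np.all(np.diff(vc) < 0)
        assert np.all(np.diff(vj) < 0)

    def test_sigma_c_is_log_base_invariant(self):
        # ratio of logs: rescaling h, h0, h1 by a common exponent cancels
        assert sigma_continuous(0.7, 1.9, 0.9) == pytest.approx(
            np.log(0.7 / 1.9) / np.log(0.9 / 1.9)
        )

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            sigma_continuous(0.0, 2.0, 1.0)
        with pytest.raises(DomainError):
            sigma_continuous(2.5, 2.0, 1.0)
        with pytest.raises(DomainError):
            sigma_continuous(1.0, 1.0, 1.0)  # h1 >= h0
        with pytest.raises(DomainError):
            sigma_jump(-0.1, 1.0)


class TestNormalizedProfile:
    def test_first_order_chain_sits_at_one(self):
        labels = sample_chain(
            np.full(4, 0.25), random_jump_matrix(4, seed=1), 100_000,
            np.random.default_rng(2),
        )
        profile = syntax_profile(MicrostateSequence(labels, 4, kind="jump"), 6)
        sigma = normalized_profile(profile, "ER").sigma
        assert np.abs(sigma - 1.0).max() < 0.05

    def test_zero_order_surrogate_sits_at_zero_continuous(self):
        # baselines h0/h1 come from a structured source (h1 < h0); a zero-order
        # surrogate of that source has empirical ER(k) ~ h0, hence sigma ~ 0
        from math import log

        from microsyntax import generate_microstate_like, make_spec, sample

        src = generate_microstate_like(4, random_jump_matrix(4, 0), 12.0, 100_000, 500.0, seed=3)
        src_prof = syntax_profile(src, 5)
        h0, h1 = src_prof.er_theory_mc0, src_prof.er_theory_mc1
        surr = sample(make_spec(src, order=0, seed=4))
        surr_prof = syntax_profile(surr, 5)
        sigma = np.array([log(h / h0) / log(h1 / h0) for h in surr_prof.er[1:]])
        assert np.abs(sigma).max() < 0.05

    def test_second_order_chain_exceeds_one(self):
        cfg = GeneratorConfig(
            n_states=4, length=20_000, order=2, seed=5,
            T2=second_order_jump_table(4), kind="jump",
        )
        profile = syntax_profile(generate_chain(cfg), 4)
        sigma = normalized_profile(profile, "ER").sigma
        assert np.all(sigma[1:] > 1.1)  # k >= 2

    def test_fully_deterministic_chain_has_degenerate_baseline(self):
        # period-2 alternation: fitted T is deterministic, h1 = 0, no valid anchor
        profile = syntax_profile(MicrostateSequence([0, 1] * 200, 2, kind="jump"), 2)
        with pytest.raises(DomainError, match="h1"):
            normalized_profile(profile, "ER")

    def test_zero_entropy_slot_maps_to_inf_with_warning(self):
        # cycle ABAC: first-order T is stochastic (h1 > 0) but order-2 contexts
        # are deterministic, so ER(2) = 0 exactly
        from microsyntax import generate_quasiperiodic

        seq = generate_quasiperiodic(3, "ABAC", 0.0, 400, seed=0)
        profile = syntax_profile(seq, 2)
        with pytest.warns(UserWarning, match="perfectly predictable"):
            out = normalized_profile(profile, "ER")
        assert np.isfinite(out.sigma[0])
        assert np.isinf(out.sigma[1])

    def test_missing_se_slots_stay_missing(self):
        seq = MicrostateSequence([3, 2, 0, 1, 3, 2, 0, 3, 2, 3, 0, 3], 4, kind="jump")
        with pytest.warns(UserWarning):
            profile = syntax_profile(seq, 5)
            out = normalized_profile(profile, "SE")
        assert profile.se_theory_mc1 > 0
        assert np.isnan(out.sigma[np.array(profile.se_status[1:]) == "undefined"]).all()
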