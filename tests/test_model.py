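"""Model grammar, probability kernels, likelihood and prior evaluation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paircomp import (
    ConfigurationError,
    ContestTable,
    DataError,
    ModelSpec,
    ParameterSet,
    PriorConfig,
    UsageError,
    bt_win_probability,
    davidson_probabilities,
    effective_ability,
    log_likelihood,
    log_prior,
)
from paircomp.model import EXTENSIONS


class TestModelGrammar:
    @pytest.mark.parametrize("name", [
        "bt", "davidson", "bt-ordereffect", "davidson-generalized-U",
        "bt-ordereffect-generalized-U-subjectpredictors",
    ])
    def test_round_trip(self, name):
        assert ModelSpec.from_string(name).name == name

    def test_extension_order_is_normalized(self):
        spec = ModelSpec.from_string("davidson-U-generalized")
        assert spec.name == "davidson-generalized-U"

    def test_unknown_extension_lists_valid_ones(self):
        with pytest.raises(ConfigurationError) as err:
            ModelSpec.from_string("bt-badext")
        for ext in EXTENSIONS:
            assert ext in str(err.value)

    def test_unknown_base_rejected(self):
        with pytest.raises(ConfigurationError, match="base"):
            ModelSpec.from_string("thurstone")

    @given(st.permutations(list(EXTENSIONS)), st.integers(0, 4),
           st.sampled_from(["bt", "davidson"]))
    @settings(deadline=None, max_examples=60)
    def test_any_extension_order_parses_losslessly(self, perm, k, base):
        name = "-".join([base] + perm[:k])
        spec = ModelSpec.from_string(name)
        assert set(spec.extensions) == set(perm[:k])
        assert ModelSpec.from_string(spec.name).name == spec.name

    def test_prior_scales_must_be_positive(self):
        with pytest.raises(ConfigurationError):
            PriorConfig(nu_sd=0.0)


class TestWinProbability:
    def test_equal_abilities_is_half(self):
        assert bt_win_probability(0.3, 0.3) == 0.5

    def test_three_prior_sd_gap(self):
        # two players three prior sds (sd = sqrt(3)) apart in each direction
        gap = 6.0 * math.sqrt(3.0)
        assert round(float(bt_win_probability(gap, 0.0)), 5) == 0.99997

    def test_order_effect_advantage_limit(self):
        # gamma -> -inf gives the first-listed player certain victory
        p = bt_win_probability(0.0, 0.0, gamma=-50.0, z=1)
        assert p > 1 - 1e-10

    def test_z_zero_disables_order_effect(self):
        assert bt_win_probability(0.2, 0.1, gamma=3.0, z=0) == \
            bt_win_probability(0.2, 0.1)

    @given(st.floats(-100, 100), st.floats(-100, 100))
    @settings(deadline=None)
    def test_complement_identity_exact(self, a, b):
        assert bt_win_probability(a, b) + bt_win_probability(b, a) == 1.0

    @given(st.floats(-4.5, 4.5), st.floats(-4.5, 4.5))
    @settings(deadline=None)
    def test_logit_is_ability_difference(self, a, b):
        # moderate gaps: beyond |difference| ~ 9 the complement 1 - p is no
        # longer representable to 1e-12 relative accuracy in a double
        p = float(bt_win_probability(a, b))
        assert math.log(p / (1 - p)) == pytest.approx(a - b, abs=1e-12)

    def test_translation_invariance(self):
        for c in (-5.0, 1.7, 5.0):
            assert bt_win_probability(1.2 + c, -0.4 + c) == pytest.approx(
                bt_win_probability(1.2, -0.4), abs=1e-10)


class TestDavidsonProbabilities:
    def test_uniform_case(self):
        p = davidson_probabilities(0.0, 0.0, nu=0.0)
        np.testing.assert_allclose(p, [1 / 3] * 3, atol=1e-15)

    def test_nu_log2_doubles_tie_weight(self):
        p_i, p_j, p_tie = davidson_probabilities(0.0, 0.0, nu=math.log(2.0))
        np.testing.assert_allclose([p_i, p_j, p_tie], [0.25, 0.25, 0.5],
                                   atol=1e-12)

    def test_nu_to_minus_inf_recovers_bradley_terry(self):
        p_i, p_j, p_tie = davidson_probabilities(1.0, 0.0, nu=-50.0)
        assert p_tie < 1e-10
        assert float(p_i) == pytest.approx(1 / (1 + math.exp(-1.0)), abs=1e-8)
        # across a grid of ability pairs
        t = np.linspace(-4, 4, 17)
        pi, pj, _ = davidson_probabilities(t, -t[::-1], nu=-50.0)
        np.testing.assert_allclose(pi, bt_win_probability(t, -t[::-1]),
                                   atol=1e-8)

    @given(st.floats(-50, 50), st.floats(-50, 50), st.floats(-20, 20))
    @settings(deadline=None)
    def test_sum_to_one(self, ti, tj, nu):
        p = np.array(davidson_probabilities(ti, tj, nu))
        assert abs(p.sum() - 1.0) < 1e-12

    @given(st.floats(-8, 8), st.floats(-8, 8), st.floats(-8, 8))
    @settings(deadline=None)
    def test_open_interval_on_representable_range(self, ti, tj, nu):
        # beyond score gaps of ~36 a double rounds the dominant probability
        # to exactly 1, so openness is only testable at moderate gaps
        p = np.array(davidson_probabilities(ti, tj, nu))
        assert np.all(p > 0) and np.all(p < 1)


class TestEffectiveAbility:
    def test_plain_identity(self):
        spec = ModelSpec.from_string("bt", n_players=2)
        params = ParameterSet(lam=np.array([0.5, -0.5]))
        assert effective_ability(spec, params, 0) == 0.5

    def test_generalized_zero_covariates(self):
        spec = ModelSpec.from_string("bt-generalized")
        params = ParameterSet(beta=np.array([2.0, -3.0]))
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        assert effective_ability(spec, params, 0, player_covariates=X) == 0.0

    def test_random_effect_is_additive(self):
        spec = ModelSpec.from_string("bt-U")
        U = np.array([[-0.3, 0.1], [0.0, 0.0]])
        params = ParameterSet(lam=np.array([1.0, 0.0]), U=U, U_std=1.0)
        assert effective_ability(spec, params, 0, subject=0) == \
            pytest.approx(0.7)

    def test_subject_required(self):
        spec = ModelSpec.from_string("bt-U")
        params = ParameterSet(lam=np.zeros(2), U=np.zeros((2, 2)), U_std=1.0)
        with pytest.raises(UsageError, match="subject"):
            effective_ability(spec, params, 0)


def _bt_table(results, p0="A", p1="B"):
    return ContestTable.from_records([p0] * len(results), [p1] * len(results),
                                     results)


class TestLogLikelihood:
    def test_even_contest_is_log_half(self):
        spec = ModelSpec.from_string("bt")
        total, pw = log_likelihood(spec, ParameterSet(lam=np.zeros(2)),
                                   _bt_table([0]))
        assert total == pytest.approx(math.log(0.5))

    def test_additivity_over_identical_contests(self):
        spec = ModelSpec.from_string("bt")
        params = ParameterSet(lam=np.array([0.7, -0.2]))
        one, _ = log_likelihood(spec, params, _bt_table([0]))
        many, pw = log_likelihood(spec, params, _bt_table([0] * 7))
        assert many == pytest.approx(7 * one)
        assert len(pw) == 7

    def test_davidson_uniform_categorical(self):
        spec = ModelSpec.from_string("davidson")
        params = ParameterSet(lam=np.zeros(2), nu=0.0)
        total, _ = log_likelihood(spec, params, _bt_table([0, 1, 2]))
        assert total == pytest.approx(3 * math.log(1 / 3))

    def test_tie_under_bt_raises(self):
        spec = ModelSpec.from_string("bt")
        with pytest.raises(DataError, match="tie"):
            log_likelihood(spec, ParameterSet(lam=np.zeros(2)),
                           _bt_table([0, 2]))

    def test_gamma_zero_matches_plain_bt_bitwise(self):
        rng = np.random.default_rng(3)
        lam = rng.normal(size=4)
        table = ContestTable.from_records(
            ["A", "B", "C", "A"], ["B", "C", "D", "D"], [0, 1, 0, 1],
            order=[1, 0, 1, 1])
        plain = ModelSpec.from_string("bt")
        ordered = ModelSpec.from_string("bt-ordereffect")
        t_plain, pw_plain = log_likelihood(plain, ParameterSet(lam=lam), table)
        t_oe, pw_oe = log_likelihood(ordered,
                                     ParameterSet(lam=lam, gamma=0.0), table)
        assert t_plain == t_oe
        assert np.array_equal(pw_plain, pw_oe)

    def test_translation_invariance_of_probabilities(self):
        spec = ModelSpec.from_string("bt")
        rng = np.random.default_rng(4)
        lam = rng.normal(size=3)
        table = ContestTable.from_records(["A", "B"], ["B", "C"], [0, 1])
        base, _ = log_likelihood(spec, ParameterSet(lam=lam), table)
        for c in (-5.0, 2.5, 5.0):
            shifted, _ = log_likelihood(spec, ParameterSet(lam=lam + c), table)
            assert shifted == pytest.approx(base, abs=1e-10)


class TestLogPrior:
    def test_standard_normal_point_density(self):
        spec = ModelSpec.from_string("bt", n_players=1,
                                     priors=PriorConfig(lambda_sd=1.0))
        lp = log_prior(spec, ParameterSet(lam=np.zeros(1)))
        assert lp == pytest.approx(math.log(1.0 / math.sqrt(2 * math.pi)))

    def test_doubling_players_doubles_terms(self):
        pri = PriorConfig(lambda_sd=1.0)
        one = log_prior(ModelSpec.from_string("bt", priors=pri),
                        ParameterSet(lam=np.zeros(2)))
        two = log_prior(ModelSpec.from_string("bt", priors=pri),
                        ParameterSet(lam=np.zeros(4)))
        assert two == pytest.approx(2 * one)

    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=6))
    @settings(deadline=None)
    def test_sign_flip_invariance(self, lam):
        spec = ModelSpec.from_string("bt")
        a = log_prior(spec, ParameterSet(lam=np.array(lam)))
        b = log_prior(spec, ParameterSet(lam=-np.array(lam)))
        assert a == pytest.approx(b, rel=1e-12)

    def test_nonpositive_u_std_rejected(self):
        spec = ModelSpec.from_string("bt-U")
        params = ParameterSet(lam=np.zeros(2), U=np.zeros((2, 2)), U_std=-1.0)
        with pytest.raises(UsageError, match="U_std"):
            log_prior(spec, params)
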