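"""Posterior sampling contracts and convergence diagnostics."""

import numpy as np
import pytest
from scipy.special import expit

import paircomp as pc
from paircomp import (
    ConfigurationError,
    ContestTable,
    ModelSpec,
    SamplerConfig,
    split_rhat,
)
from paircomp.inference import (
    apply_diagnostic_rules,
    check_convergence_diagnostics,
    e_bfmi,
    effective_sample_size,
)


def two_player_data(wins_a=80, n=100):
    results = [0] * wins_a + [1] * (n - wins_a)
    return ContestTable.from_records(["A"] * n, ["B"] * n, results)


def grid_posterior_mean_contrast(wins_a, n, prior_sd):
    """Independent oracle: numeric integration over d = lambda_A - lambda_B.

    The two iid normal priors on the abilities induce d ~ N(0, 2 sd^2) and
    the likelihood depends on d alone, so the joint posterior factorizes
    and the 1-D grid is exact for the contrast.
    """
    d = np.linspace(-10, 10, 40001)
    log_post = (
        -0.5 * d**2 / (2 * prior_sd**2)
        + wins_a * np.log(expit(d))
        + (n - wins_a) * np.log(expit(-d))
    )
    w = np.exp(log_post - log_post.max())
    return float(np.sum(d * w) / np.sum(w))


class TestSamplePosterior:
    def test_two_player_contrast_matches_grid_oracle(self):
        spec = ModelSpec.from_string("bt")
        data = two_player_data()
        draws = pc.sample_posterior(
            spec, data, SamplerConfig(chains=2, iterations=1500, warmup=500,
                                      seed=31))
        lam = draws.stacked("lambda")
        contrast = float((lam[:, 0] - lam[:, 1]).mean())
        oracle = grid_posterior_mean_contrast(80, 100,
                                              spec.priors.lambda_sd)
        assert contrast == pytest.approx(oracle, abs=0.1)
        # large-data posterior sits near the MLE logit(0.8) = 1.386
        assert contrast == pytest.approx(np.log(4.0), abs=0.15)

    def test_prior_only_posterior_recovers_prior_moments(self):
        spec = ModelSpec.from_string("bt")
        empty = ContestTable(player0=(), player1=(),
                             result=np.zeros(0, dtype=np.int64),
                             players=("A", "B"))
        draws = pc.sample_posterior(
            spec, empty, SamplerConfig(chains=4, iterations=1500, warmup=500,
                                       seed=5))
        lam = draws.stacked("lambda")
        sd = spec.priors.lambda_sd
        for k in range(2):
            ess = effective_sample_size(draws.params["lambda"][:, :, k])
            mcse = sd / np.sqrt(ess)
            assert abs(lam[:, k].mean()) < 3 * mcse
            assert lam[:, k].std() == pytest.approx(sd, rel=0.10)

    def test_same_seed_is_bit_identical(self):
        spec = ModelSpec.from_string("bt")
        data = two_player_data(30, 50)
        config = SamplerConfig(chains=2, iterations=400, warmup=200, seed=77)
        a = pc.sample_posterior(spec, data, config)
        b = pc.sample_posterior(spec, data, config)
        assert np.array_equal(a.params["lambda"], b.params["lambda"])
        assert np.array_equal(a.stats["energy"], b.stats["energy"])

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            SamplerConfig(warmup=2000, iterations=1000)


class TestSplitRhat:
    def test_iid_chains_are_converged(self):
        rng = np.random.default_rng(0)
        arr = rng.standard_normal((4, 1000))
        assert split_rhat(arr) < 1.01

    def test_matches_arviz_rank_normalized(self):
        import arviz as az

        rng = np.random.default_rng(1)
        arr = rng.standard_normal((4, 500)) + rng.normal(
            0, 0.2, size=(4, 1))  # mild chain offsets
        assert split_rhat(arr) == pytest.approx(
            float(az.rhat(arr)), abs=1e-6)

    def test_non_mixing_chains_flagged(self):
        arr = np.vstack([np.zeros(100), np.full(100, 10.0)])
        assert split_rhat(arr) > 100  # far beyond the 1.01 threshold
        assert split_rhat(arr, rank_normalized=False) == np.inf

    def test_all_identical_draws_degenerate(self):
        arr = np.full((2, 100), 3.14)
        assert np.isnan(split_rhat(arr))

    def test_duplicated_chain_matches_hand_formula(self):
        # one 4-value chain duplicated; plain split formula by hand:
        # half-chains [a,b],[c,d],[a,b],[c,d]
        a, b, c, d = 1.0, 2.0, 4.0, 8.0
        halves = np.array([[a, b], [c, d], [a, b], [c, d]])
        n = 2
        w = halves.var(axis=1, ddof=1).mean()
        bvar = n * halves.mean(axis=1).var(ddof=1)
        expected = np.sqrt(((n - 1) / n * w + bvar / n) / w)
        got = split_rhat(np.array([[a, b, c, d], [a, b, c, d]]),
                         rank_normalized=False)
        assert got == pytest.approx(expected, abs=1e-6)

    def test_too_few_chains_rejected(self):
        with pytest.raises(pc.UsageError):
            split_rhat(np.zeros((1, 100)))


class TestDiagnosticRules:
    BASE = dict(rhat={"x": 1.0}, ess={"x": 1000.0}, n_divergent=0,
                treedepth_hits=0, ebfmi=np.array([1.0]))

    def _run(self, **overrides):
        args = {**self.BASE, **overrides}
        return apply_diagnostic_rules(**args)

    def test_clean_run_passes(self):
        passed, reasons, warnings = self._run()
        assert passed and not reasons and not warnings

    @pytest.mark.parametrize("rhat,ok", [(1.0099, True), (1.01, False),
                                         (1.5, False)])
    def test_rhat_boundary(self, rhat, ok):
        assert self._run(rhat={"x": rhat})[0] is ok

    @pytest.mark.parametrize("ess,ok", [(200.0, True), (199.9, False),
                                        (150.0, False)])
    def test_ess_boundary(self, ess, ok):
        passed, reasons, _ = self._run(ess={"x": ess})
        assert passed is ok
        if not ok:
            assert any("200" in r for r in reasons)

    @pytest.mark.parametrize("bfmi,ok", [(0.2, True), (0.199, False)])
    def test_ebfmi_boundary(self, bfmi, ok):
        assert self._run(ebfmi=np.array([bfmi]))[0] is ok

    def test_any_divergence_fails(self):
        passed, reasons, _ = self._run(n_divergent=1)
        assert not passed and any("divergent" in r for r in reasons)

    def test_treedepth_hits_warn_but_pass(self):
        passed, reasons, warnings = self._run(treedepth_hits=3)
        assert passed and not reasons
        assert any("treedepth" in w for w in warnings)


class TestCheckConvergenceDiagnostics:
    def test_well_mixed_run_passes(self, bt_fit):
        _, _, _, draws = bt_fit
        diag = check_convergence_diagnostics(draws)
        assert diag.passed, diag.reasons

    def test_injected_divergences_fail_with_reason(self, bt_fit):
        import copy

        _, _, _, draws = bt_fit
        tweaked = copy.copy(draws)
        tweaked.stats = {k: v.copy() for k, v in draws.stats.items()}
        tweaked.stats["divergent"][0, :3] = True
        diag = check_convergence_diagnostics(tweaked)
        assert not diag.passed
        assert any("divergent" in r for r in diag.reasons)

    def test_report_renders(self, bt_fit):
        _, _, _, draws = bt_fit
        text = check_convergence_diagnostics(draws).to_text()
        assert "verdict" in text and "lambda[P1]" in text


class TestEBfmi:
    def test_white_noise_energy_is_high(self):
        rng = np.random.default_rng(2)
        assert e_bfmi(rng.standard_normal((1, 2000)))[0] > 0.8

    def test_random_walk_energy_is_low(self):
        rng = np.random.default_rng(3)
        walk = np.cumsum(rng.standard_normal(2000))[None, :] * 0.05
        assert e_bfmi(walk)[0] < 0.2
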