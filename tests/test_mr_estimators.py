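"""Wald ratio, IVW, OR/CI/p reporting and the reverse-causation screen."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.stats import norm

from mrscreen import (
    HarmonizedSet,
    SimConfig,
    harmonize,
    ivw,
    or_ci_p,
    reverse_screen,
    select_instruments,
    simulate_study,
    wald_ratio,
)

from conftest import estimate_replicate, make_table, subset_table


def hset_from(beta_exp, se_exp, beta_out, se_out):
    df = pd.DataFrame(
        {
            "variant_id": [f"rs{i}" for i in range(len(beta_exp))],
            "beta_exp": beta_exp,
            "se_exp": se_exp,
            "beta_out": beta_out,
            "se_out": se_out,
            "eaf_exp": 0.3,
        }
    )
    return HarmonizedSet("exp", "out", df)


class TestWaldRatio:
    def test_basic_ratio(self):
        res = wald_ratio(0.1, 0.01, 0.2, 0.05)
        assert res.beta_mr == pytest.approx(2.0)
        assert res.method == "wald_ratio"

    def test_null_outcome(self):
        res = wald_ratio(0.1, 0.01, 0.0, 0.05)
        assert res.beta_mr == 0.0
        assert res.pval == 1.0

    def test_degenerate_instrument_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            wald_ratio(0.0, 0.01, 0.2, 0.05)

    def test_se_against_monte_carlo(self, rng):
        """First-order delta-method SE of the ratio agrees with the sampling
        SD of beta_out/beta_exp over 1e5 draws when se_exp is small."""
        beta_exp, beta_out, se_out = 0.05, -0.03, 0.01
        res = wald_ratio(beta_exp, 1e-6, beta_out, se_out)
        assert res.beta_mr == pytest.approx(-0.6)
        assert res.se_mr == pytest.approx(0.2)
        draws = rng.normal(beta_out, se_out, size=100_000) / beta_exp
        assert draws.std() == pytest.approx(res.se_mr, rel=0.02)


class TestIVW:
    def test_closed_form_two_snp(self):
        res = ivw(hset_from([1.0, 1.0], [0.01, 0.01], [0.2, 0.4], [1.0, 1.0]))
        assert res.beta_mr == pytest.approx(0.3)
        assert res.se_mr == pytest.approx(1 / math.sqrt(2))
        assert res.method == "ivw_fe"
        assert res.n_snp == 2

    def test_single_variant_routes_to_wald(self):
        h = hset_from([0.1], [0.01], [0.2], [0.05])
        res = ivw(h)
        ref = wald_ratio(0.1, 0.01, 0.2, 0.05)
        assert res.method == "wald_ratio"
        assert res.beta_mr == ref.beta_mr and res.se_mr == ref.se_mr

    def test_duplicating_instruments_halves_variance(self):
        bx, sx, by, so = [0.1, 0.2, 0.15], [0.01] * 3, [0.03, 0.05, 0.04], [0.02] * 3
        single = ivw(hset_from(bx, sx, by, so))
        double = ivw(hset_from(bx * 2, sx * 2, by * 2, so * 2))
        assert double.beta_mr == pytest.approx(single.beta_mr)
        assert double.se_mr == pytest.approx(single.se_mr / math.sqrt(2))

    def test_random_effects_inflates_se_under_heterogeneity(self):
        h = hset_from([1.0, 1.0, 1.0], [0.01] * 3, [0.1, 0.5, 0.9], [0.05] * 3)
        fe, re = ivw(h, "fe"), ivw(h, "re")
        assert re.beta_mr == fe.beta_mr
        assert re.se_mr > fe.se_mr
        assert fe.q_stat > 2 and fe.q_pval < 0.05

    def test_random_effects_never_deflates(self):
        h = hset_from([1.0, 1.0], [0.01] * 2, [0.3, 0.3], [0.05] * 2)
        assert ivw(h, "re").se_mr == ivw(h, "fe").se_mr  # Q/(n-1) < 1 clamps

    def test_equals_weighted_least_squares(self):
        """IVW is the intercept-free WLS slope of beta_out on beta_exp with
        weights 1/se_out² (independent statsmodels fit)."""
        for seed in range(5):
            cfg = SimConfig(theta_dir=0.25, seed=seed)
            exposure, _, outcome, ld, _ = simulate_study(cfg)
            kept, _ = select_instruments(exposure, ld)
            sub = subset_table(exposure, kept)
            h = harmonize(sub, outcome)
            res = ivw(h)
            fit = sm.WLS(
                h.df["beta_out"], h.df[["beta_exp"]],
                weights=1.0 / h.df["se_out"] ** 2,
            ).fit()
            assert res.beta_mr == pytest.approx(fit.params["beta_exp"], rel=1e-10)

    def test_sign_equivariance_under_reorientation(self):
        """Flipping every allele (negating both betas) leaves the causal
        estimate unchanged."""
        bx = [0.1, -0.2, 0.15]
        by = [0.03, -0.05, 0.04]
        a = ivw(hset_from(bx, [0.01] * 3, by, [0.02] * 3))
        b = ivw(hset_from([-x for x in bx], [0.01] * 3,
                          [-y for y in by], [0.02] * 3))
        assert a.beta_mr == pytest.approx(b.beta_mr)
        assert a.se_mr == pytest.approx(b.se_mr)


class TestOrCiP:
    def test_null_beta(self):
        or_, lo, hi, p = or_ci_p(0.0, 0.1)
        assert or_ == 1.0 and p == 1.0
        assert lo * hi == pytest.approx(1.0)  # symmetric about 1 on log scale

    def test_exact_p05_round_trip(self):
        z = norm.ppf(0.975)
        _, _, _, p = or_ci_p(math.log(2), math.log(2) / z)
        assert p == pytest.approx(0.05, rel=1e-10)

    def test_invalid_se_rejected(self):
        with pytest.raises(ValueError):
            or_ci_p(0.1, 0.0)

    def test_ci_brackets_or(self):
        or_, lo, hi, _ = or_ci_p(-0.3, 0.08)
        assert lo < or_ < hi
        assert or_ == pytest.approx(math.exp(-0.3))


class TestReverseScreen:
    def _study(self, seed, reverse=False):
        """Outcome with its own instruments; exposure optionally downstream
        of the outcome (reverse causation)."""
        rng = np.random.default_rng(seed)
        n = 50
        ids = [f"rs{i}" for i in range(n)]
        maf = rng.uniform(0.1, 0.5, n)
        se_out = 1 / np.sqrt(2 * maf * (1 - maf) * 20_000)
        se_exp = 1 / np.sqrt(2 * maf * (1 - maf) * 35_553)
        b_out = np.zeros(n)
        b_out[:10] = rng.normal(0, 0.15, 10)  # outcome instruments
        theta_rev = 0.8 if reverse else 0.0
        b_exp = theta_rev * b_out
        bo = b_out + rng.normal(0, se_out)
        be = b_exp + rng.normal(0, se_exp)
        p_out = 2 * norm.sf(np.abs(bo) / se_out)
        p_exp = 2 * norm.sf(np.abs(be) / se_exp)
        out_rows = [
            (ids[i], "A", "G", maf[i], bo[i], se_out[i], max(p_out[i], 1e-300), 20000)
            for i in range(n)
        ]
        exp_rows = [
            (ids[i], "A", "G", maf[i], be[i], se_exp[i], max(p_exp[i], 1e-300), 35553)
            for i in range(n)
        ]
        from mrscreen import LDMatrix

        return (
            make_table(out_rows, "myocarditis", "outcome"),
            make_table(exp_rows, "protein", "exposure"),
            LDMatrix(ids, np.eye(n)),
        )

    def test_no_exposures_gives_empty(self):
        outcome, _, ld = self._study(0)
        assert reverse_screen(outcome, [], ld) == []

    def test_no_outcome_instruments_warns_and_returns_empty(self):
        outcome, exposure, ld = self._study(1)
        outcome.df["pval"] = 0.5
        with pytest.warns(UserWarning, match="no instruments"):
            assert reverse_screen(outcome, [exposure], ld) == []

    def test_reverse_causal_exposure_flagged(self):
        hits = 0
        for seed in range(20):
            outcome, exposure, ld = self._study(seed, reverse=True)
            if reverse_screen(outcome, [exposure], ld) == ["protein"]:
                hits += 1
        assert hits >= 18  # >= 90% power at this effect size

    def test_forward_only_flag_rate_near_alpha(self):
        flags = 0
        for seed in range(100, 300):
            outcome, exposure, ld = self._study(seed, reverse=False)
            flags += len(reverse_screen(outcome, [exposure], ld))
        # 200 null replicates at p_flag = 0.05: expect ~10 flags
        assert 2 <= flags <= 22


class TestTypeIAndRecovery:
    def test_parameter_recovery_quick(self):
        """Mean IVW estimate near theta_total over 100 replicates (the full
        500-replicate run lives in the acceptance suite)."""
        ests = []
        for seed in range(100):
            cfg = SimConfig(theta_dir=0.3, seed=seed)
            res, truth = estimate_replicate(cfg)
            if res is not None:
                ests.append(res.beta_mr)
        mean = np.mean(ests)
        mc_se = np.std(ests) / math.sqrt(len(ests))
        assert abs(mean - 0.3) < 3 * mc_se + 0.01
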