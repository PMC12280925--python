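"""Model equations, single-curve fits, and screen statistics."""

import numpy as np
import pandas as pd
import pytest
import sympy

from allomod.datatypes import (
    ATCMParams,
    CompetitionBindingDataset,
    HillParams,
    OneSiteFit,
    OperationalParams,
)
from allomod.pharm_models import (
    call_hits,
    fit_hill,
    fit_one_site,
    ki_from_ic50,
    normalize_camp,
    predict_atcm,
    predict_hill,
    predict_one_site,
    predict_operational,
    screen_deltas,
)


# ---------------------------------------------------------------------------
# One-site displacement


class TestOneSite:
    def test_asymptote_and_midpoint(self):
        p = OneSiteFit(top=95.0, bottom=12.0, log_ic50=-7.3)
        assert predict_one_site(p, -np.inf) == pytest.approx(95.0)
        assert predict_one_site(p, p.log_ic50) == pytest.approx((95.0 + 12.0) / 2)

    def test_matches_symbolic_evaluation(self, rng):
        """Arbitrary params/x agree with extended-precision symbolic evaluation."""

        X, top, bot, logic = sympy.symbols("X top bot logic")
        expr = bot + (top - bot) / (1 + 10 ** (X - logic))
        for _ in range(20):
            t, b = sorted(rng.uniform(0, 100, 2))[::-1]
            li = rng.uniform(-10, -5)
            x = rng.uniform(-11, -4)
            expected = float(
                expr.evalf(30, subs={X: x, top: t, bot: b, logic: li})
            )
            p = OneSiteFit(top=t, bottom=b, log_ic50=li)
            assert predict_one_site(p, x) == pytest.approx(expected, rel=1e-12)

    def test_zero_noise_recovery(self):
        truth = OneSiteFit(top=100.0, bottom=5.0, log_ic50=-7.0)
        concs = np.logspace(-10, -4, 13)
        data = CompetitionBindingDataset(
            radioligand_conc=1e-9,
            competitor_concs=concs,
            specific_binding=predict_one_site(truth, np.log10(concs)),
        )
        fit = fit_one_site(data)
        assert fit.converged
        assert fit.params.log_ic50 == pytest.approx(truth.log_ic50, abs=1e-6)
        assert fit.params.top == pytest.approx(truth.top, abs=1e-6)

    def test_noisy_recovery_within_3se(self):
        truth = OneSiteFit(top=100.0, bottom=5.0, log_ic50=-7.0)
        rng = np.random.default_rng(77)
        concs = np.repeat(np.logspace(-10, -4, 20), 10)  # 200 points
        y = predict_one_site(truth, np.log10(concs))
        y = y * (1 + rng.normal(0, 0.05, y.shape))
        fit = fit_one_site(
            CompetitionBindingDataset(1e-9, concs, y), seed=3
        )
        assert fit.converged
        se = fit.standard_errors["log_ic50"]
        assert abs(fit.params.log_ic50 - truth.log_ic50) < 3 * se

    def test_flat_curve_flagged(self):
        data = CompetitionBindingDataset(
            radioligand_conc=1e-9,
            competitor_concs=np.logspace(-9, -5, 8),
            specific_binding=np.full(8, 50.0),
        )
        fit = fit_one_site(data)
        assert not fit.converged
        assert fit.reason == "flat_curve"
        assert fit.params is None


class TestChengPrusoff:
    def test_limit_and_arithmetic(self):
        assert ki_from_ic50(2e-8, 0.0, 1e-9) == pytest.approx(2e-8)
        assert ki_from_ic50(10e-9, 1e-9, 1e-9) == pytest.approx(5e-9)

    def test_random_triples_match_formula(self, rng):
        for _ in range(25):
            ic50, a, kd = 10.0 ** rng.uniform(-9, -5, 3)
            assert ki_from_ic50(ic50, a, kd) == pytest.approx(ic50 / (1 + a / kd), rel=1e-14)

    @pytest.mark.parametrize("bad", [(0, 1e-9, 1e-9), (1e-8, -1e-9, 1e-9), (1e-8, 1e-9, 0)])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(ValueError):
            ki_from_ic50(*bad)


# ---------------------------------------------------------------------------
# Allosteric ternary complex model


def _atcm_params(**kw) -> ATCMParams:
    base = dict(bmax=200.0, pKA=9.0, pKB=5.0, pKI=6.5, log_alpha_A=-0.2, log_alpha_I=1.5)
    base.update(kw)
    return ATCMParams(**base)


class TestATCM:
    def test_reduces_to_competitive_binding_at_b_zero(self, rng):
        """With no modulator the ATCM is two-ligand competition, exactly."""

        p = _atcm_params()
        a = 1e-9
        i = 10.0 ** rng.uniform(-10, -5, 50)
        ka, ki = 10.0 ** -p.pKA, 10.0 ** -p.pKI
        competitive = p.bmax * a / (a + ka * (1 + i / ki))
        np.testing.assert_allclose(
            predict_atcm(p, a, i, np.zeros_like(i)), competitive, rtol=1e-14
        )

    def test_neutral_cooperativity_is_constant_in_b(self):
        p = _atcm_params(log_alpha_A=0.0, log_alpha_I=0.0)
        b = np.logspace(-9, -3, 40)
        y = predict_atcm(p, 1e-9, 1e-7, b)
        assert np.max(np.abs(y - y[0])) < 1e-10 * abs(y[0])

    def test_matches_symbolic_expression(self, rng):
        """Grid of parameters agrees with an independent symbolic evaluation."""

        A, B, I, bmax, ka, kb, ki, aa, ai = sympy.symbols(
            "A B I bmax ka kb ki aa ai", positive=True
        )
        expr = bmax * A / (
            A
            + (ka * kb / (aa * B + kb))
            * (1 + I / ki + B / kb + ai * I * B / (ki * kb))
        )
        for _ in range(15):
            p = _atcm_params(
                pKB=rng.uniform(4, 7),
                pKI=rng.uniform(5, 8),
                log_alpha_A=rng.uniform(-1, 1),
                log_alpha_I=rng.uniform(-2, 2),
            )
            a_v, i_v, b_v = 10.0 ** rng.uniform(-9, -5, 3)
            subs = {
                A: a_v, B: b_v, I: i_v, bmax: p.bmax,
                ka: 10.0 ** -p.pKA, kb: 10.0 ** -p.pKB, ki: 10.0 ** -p.pKI,
                aa: 10.0 ** p.log_alpha_A, ai: 10.0 ** p.log_alpha_I,
            }
            expected = float(expr.evalf(30, subs=subs))
            assert predict_atcm(p, a_v, i_v, b_v) == pytest.approx(expected, rel=1e-12)

    def test_displacement_ic50_decreases_with_modulator(self):
        """Positive agonist cooperativity shifts displacement curves leftward."""

        from scipy.optimize import brentq

        p = _atcm_params(log_alpha_I=1.5)
        a = 1e-9

        def apparent_ic50(b):
            top = predict_atcm(p, a, 0.0, b)
            bottom = predict_atcm(p, a, 1e-2, b)  # saturating agonist
            half = (top + bottom) / 2

            return brentq(lambda i: predict_atcm(p, a, i, b) - half, 1e-13, 1e-2)

        ic50s = [apparent_ic50(b) for b in [0.0, 1e-6, 3e-6, 1e-5, 3e-5]]
        assert all(x > y for x, y in zip(ic50s, ic50s[1:]))

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            predict_atcm(_atcm_params(), 1e-9, -1e-9, 0.0)


# ---------------------------------------------------------------------------
# Operational model of allosterism


def _op_params(**kw) -> OperationalParams:
    base = dict(
        em=100.0, pKA=6.5, pKB=5.0, log_tau_A=1.0, log_tau_B=-0.5,
        log_alpha=1.0, log_beta=-0.3, n=1.0,
    )
    base.update(kw)
    return OperationalParams(**base)


class TestOperational:
    def test_reduces_to_operational_agonism_at_b_zero(self, rng):
        for n in (1.0, 1.7):
            p = _op_params(n=n)
            a = 10.0 ** rng.uniform(-10, -4, 30)
            ka, tau_a = 10.0 ** -p.pKA, 10.0 ** p.log_tau_A
            closed = p.em * tau_a**n * a**n / ((a + ka) ** n + tau_a**n * a**n)
            np.testing.assert_allclose(
                predict_operational(p, a, np.zeros_like(a)), closed, rtol=1e-14
            )

    def test_zero_everywhere_without_agonist_or_efficacy(self):
        p = _op_params(log_tau_B=-30.0)  # tau_B -> 0 limit
        b = np.logspace(-8, -4, 10)
        assert np.all(predict_operational(p, np.zeros_like(b), b) < 1e-20)

    def test_allosteric_agonism_closed_form(self, rng):
        """A = 0, tau_B > 0 reduces to the modulator's own operational curve."""

        for n in (1.0, 2.0):
            p = _op_params(n=n, log_tau_B=0.3)
            b = 10.0 ** rng.uniform(-8, -3, 30)
            kb, tau_b = 10.0 ** -p.pKB, 10.0 ** p.log_tau_B
            closed = p.em * tau_b**n * b**n / ((b + kb) ** n + tau_b**n * b**n)
            np.testing.assert_allclose(
                predict_operational(p, np.zeros_like(b), b), closed, rtol=1e-14
            )

    def test_composite_alphabeta(self):
        p = _op_params(log_alpha=1.0, log_beta=-0.32)
        assert p.log_alphabeta == pytest.approx(0.68)


# ---------------------------------------------------------------------------
# Hill fits and normalization


class TestHill:
    def test_noiseless_recovery(self):
        truth = HillParams(basal=2.0, emax=98.0, pEC50=6.9)
        a = np.logspace(-11, -4, 15)
        fit = fit_hill(a, predict_hill(truth, a))
        assert fit.converged
        assert fit.params.pEC50 == pytest.approx(6.9, abs=1e-6)
        assert fit.params.emax == pytest.approx(98.0, abs=1e-4)

    def test_atrial_potency_curve_recovered(self):
        """A curve generated at EC50 = 0.13 µM is read back as pEC50 ~ 6.89."""

        truth = HillParams(basal=0.0, emax=100.0, pEC50=-np.log10(0.13e-6))
        a = np.logspace(-9, -4.5, 12)
        rng = np.random.default_rng(5)
        y = predict_hill(truth, a) * (1 + rng.normal(0, 0.03, a.shape))
        fit = fit_hill(a, y, seed=2)
        assert fit.converged
        assert fit.params.pEC50 == pytest.approx(6.886, abs=0.15)

    def test_matches_formula_oracle(self, rng):
        p = HillParams(basal=10.0, emax=90.0, pEC50=7.2)
        a = 10.0 ** rng.uniform(-10, -5, 20)
        ec50 = 10.0 ** -p.pEC50
        np.testing.assert_allclose(
            predict_hill(p, a), 10.0 + 80.0 * a / (ec50 + a), rtol=1e-14
        )

    def test_flat_curve_flagged(self):
        fit = fit_hill(np.logspace(-9, -5, 8), np.full(8, 42.0))
        assert not fit.converged and fit.reason == "flat_curve"


class TestNormalizeCamp:
    def test_anchors_and_linearity(self):
        assert normalize_camp(1200.0, 1200.0, 400.0) == pytest.approx(0.0)
        assert normalize_camp(400.0, 1200.0, 400.0) == pytest.approx(100.0)
        assert normalize_camp(800.0, 1200.0, 400.0) == pytest.approx(50.0)

    def test_identical_references_rejected(self):
        with pytest.raises(ValueError):
            normalize_camp(1.0, 5.0, 5.0)


# ---------------------------------------------------------------------------
# Screen statistics


def _screen_frames(deltas_by_compound, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    ctrl_rows, trt_rows = [], []
    for cid, (reps_pki, reps_pec) in deltas_by_compound.items():
        for r, (dk, dp) in enumerate(zip(reps_pki, reps_pec)):
            base_k = 6.5 + noise * rng.normal()
            base_p = 7.5 + noise * rng.normal()
            ctrl_rows.append({"compound_id": cid, "replicate": f"r{r}", "pKI": base_k, "pEC50": base_p})
            trt_rows.append({"compound_id": cid, "replicate": f"r{r}", "pKI": base_k + dk, "pEC50": base_p + dp})
    return pd.DataFrame(ctrl_rows), pd.DataFrame(trt_rows)


class TestScreenStats:
    def test_matches_closed_form_t(self):
        """Δ replicates {0.5, 0.6, 0.7} reproduce the textbook one-sample t."""

        deltas = [0.5, 0.6, 0.7]
        control, treated = _screen_frames({"c1": (deltas, deltas)})
        summary = screen_deltas(control, treated)
        # textbook: t = mean / (sd / sqrt(n)); p from t_{n-1}, two-sided
        from scipy.stats import t as t_dist

        m, sd, n = np.mean(deltas), np.std(deltas, ddof=1), 3
        t_stat = m / (sd / np.sqrt(n))
        p_expected = 2 * t_dist.sf(abs(t_stat), n - 1)
        row = summary.iloc[0]
        assert row["delta_pKI"] == pytest.approx(0.6)
        assert row["p_value_affinity"] == pytest.approx(p_expected, rel=1e-10)
        assert row["hit_flag"]

    def test_zero_variance_not_a_hit(self):
        control, treated = _screen_frames({"c1": ([0.0] * 3, [0.0] * 3)})
        summary = screen_deltas(control, treated)
        assert np.isnan(summary.iloc[0]["p_value_affinity"])
        assert not summary.iloc[0]["hit_flag"]

    def test_unmatched_replicates_rejected(self):
        control, treated = _screen_frames({"c1": ([0.1] * 3, [0.1] * 3)})
        with pytest.raises(ValueError):
            screen_deltas(control.iloc[:-1], treated)

    def test_fewer_than_three_replicates_rejected(self):
        control, treated = _screen_frames({"c1": ([0.1] * 2, [0.1] * 2)})
        with pytest.raises(ValueError):
            screen_deltas(control, treated)

    @pytest.mark.parametrize(
        "n_hits,expected_rate", [(3, 11.5), (1, 3.8), (0, 0.0)]
    )
    def test_hit_rates_to_one_decimal(self, n_hits, expected_rate):
        """3 / 1 / 0 hits among 26 tested give 11.5% / 3.8% / 0.0%."""

        spec = {}
        for i in range(26):
            d = [0.5, 0.55, 0.6, 0.5] if i < n_hits else [0.0, 0.01, -0.01, 0.0]
            spec[f"c{i:02d}"] = (d, d)
        control, treated = _screen_frames(spec)
        summary = screen_deltas(control, treated)
        hits, rate = call_hits(summary)
        assert len(hits) == n_hits
        assert rate == expected_rate

    def test_empty_summary_rejected(self):
        with pytest.raises(ValueError):
            call_hits(pd.DataFrame(columns=["compound_id"]))
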