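import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import minimize
from sklearn.base import clone

from rhythmoscope import (
    CosinorRegressor,
    GeneSpec,
    StudyDesign,
    acrophase_to_zt,
    amplitude_se,
    classify_rhythmic,
    cosinor_signal,
    fit_cosinor,
    generate_expression_dataset,
    rhythm_table,
)


def _noisy(times, mesor, amplitude, acrophase, noise_sd, rng):
    signal = cosinor_signal(times, mesor, amplitude, acrophase)
    return signal * 2.0 ** rng.normal(0.0, noise_sd, times.size)


class TestFitCosinor:
    @pytest.mark.parametrize(
        "mesor, amplitude, acrophase",
        [(0.5, 0.3, 2.0), (1.0, 0.0, 0.0), (2.5, 1.0, 5.9), (0.3, 0.29, math.pi)],
    )
    def test_noiseless_recovery(self, times54, mesor, amplitude, acrophase):
        y = cosinor_signal(times54, mesor, amplitude, acrophase)
        fit = fit_cosinor(times54, y)
        assert fit.mesor == pytest.approx(mesor, abs=1e-6)
        assert fit.amplitude == pytest.approx(amplitude, abs=1e-6)
        if amplitude > 0:
            assert fit.acrophase_rad == pytest.approx(acrophase, abs=1e-6)
            assert fit.p_ns == pytest.approx(0.0, abs=1e-6)

    def test_constant_series_has_zero_amplitude(self, times9):
        fit = fit_cosinor(times9, np.full_like(times9, 3.0))
        assert fit.mesor == pytest.approx(3.0)
        assert fit.amplitude == pytest.approx(0.0, abs=1e-12)
        assert math.isinf(fit.p_ns) and not fit.rhythmic

    def test_model_basis_vector(self, times9):
        fit = fit_cosinor(times9, np.cos(math.pi * times9 / 12.0))
        assert fit.mesor == pytest.approx(0.0, abs=1e-12)
        assert fit.amplitude == pytest.approx(1.0)
        assert fit.acrophase_rad == pytest.approx(0.0, abs=1e-9)

    def test_amplitude_is_norm_of_coefficients(self, times54):
        rng = np.random.default_rng(3)
        fit = fit_cosinor(times54, _noisy(times54, 1.0, 0.4, 1.0, 0.2, rng))
        assert fit.amplitude == pytest.approx(math.hypot(fit.beta, fit.gamma))
        assert fit.acrophase_zt == pytest.approx(
            (fit.acrophase_rad * 12 / math.pi) % 24
        )

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            fit_cosinor([0, 6, 12], [1, 2, 1])

    def test_degenerate_phases_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_cosinor([0, 24, 0, 24], [1, 2, 1, 2])
        with pytest.raises(ValueError, match="degenerate"):
            fit_cosinor([0, 12, 24, 36], [1, 2, 1, 2])  # two distinct phases

    def test_brute_force_least_squares_oracle(self, times9):
        """(M, beta, gamma) agree with a direct RSS minimisation."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = rng.integers(6, 12)
            t = rng.uniform(0, 24, n)
            t[:3] = [0, 8, 16]  # guarantee identifiable phases
            y = rng.uniform(0, 2, n)
            fit = fit_cosinor(t, y)

            def rss(p):
                m, b, g = p
                pred = m + b * np.cos(math.pi * t / 12) + g * np.sin(math.pi * t / 12)
                return float(((y - pred) ** 2).sum())

            # coarse grid then simplex refinement, independent of the OLS path
            grid = [
                (m, b, g)
                for m in np.linspace(y.min(), y.max(), 5)
                for b in np.linspace(-2, 2, 5)
                for g in np.linspace(-2, 2, 5)
            ]
            start = min(grid, key=rss)
            best = minimize(rss, start, method="Nelder-Mead",
                            options=dict(xatol=1e-8, fatol=1e-12, maxiter=5000))
            np.testing.assert_allclose(
                [fit.mesor, fit.beta, fit.gamma], best.x, atol=1e-4
            )


class TestAmplitudeSE:
    def test_noiseless_fit_has_zero_se(self, times54):
        fit = fit_cosinor(times54, cosinor_signal(times54, 1.0, 0.5, 1.0))
        assert amplitude_se(fit) == pytest.approx(0.0, abs=1e-9)

    def test_zero_amplitude_degenerate(self, times9):
        fit = fit_cosinor(times9, np.full_like(times9, 1.0))
        with pytest.raises(ZeroDivisionError):
            amplitude_se(fit)

    def test_balanced_design_se_equals_coefficient_se(self):
        """Without the duplicated ZT0/ZT24 phase the harmonic basis is
        exactly balanced: Var(beta) = Var(gamma), Cov = 0, so SE(A)
        equals the coefficient SE regardless of the phase."""
        t = np.repeat(np.arange(0.0, 24.0, 3.0), 6)  # 8 distinct phases
        rng = np.random.default_rng(5)
        fit = fit_cosinor(t, _noisy(t, 1.0, 0.4, 2.3, 0.15, rng))
        cov = fit.coef_covariance
        assert cov[1, 1] == pytest.approx(cov[2, 2], rel=1e-9)
        assert cov[1, 2] == pytest.approx(0.0, abs=1e-12)
        assert amplitude_se(fit) == pytest.approx(math.sqrt(cov[1, 1]), rel=1e-9)

    def test_nine_point_design_se_between_coefficient_ses(self, times54):
        # the duplicated ZT0/ZT24 phase makes Var(beta) < Var(gamma)
        rng = np.random.default_rng(6)
        fit = fit_cosinor(times54, _noisy(times54, 1.0, 0.4, 2.3, 0.15, rng))
        cov = fit.coef_covariance
        lo, hi = sorted([math.sqrt(cov[1, 1]), math.sqrt(cov[2, 2])])
        assert lo <= amplitude_se(fit) <= hi

    def test_monte_carlo_sd_matches_delta_method(self, times54):
        """SD of A over 2000 refits within 15% of the delta-method SE."""
        rng = np.random.default_rng(42)
        amplitudes, ses = [], []
        for _ in range(2000):
            fit = fit_cosinor(times54, _noisy(times54, 0.5, 0.25, 2.0, 0.1, rng))
            amplitudes.append(fit.amplitude)
            ses.append(fit.se_amplitude)
        assert np.std(amplitudes) == pytest.approx(np.mean(ses), rel=0.15)


class TestClassification:
    @pytest.mark.parametrize(
        "p_ns, expected",
        [(0.21, True), (0.46, False), (0.3, False), (0.299, True), (math.inf, False)],
    )
    def test_strict_threshold(self, p_ns, expected):
        assert classify_rhythmic(p_ns) is expected

    def test_negative_p_rejected(self):
        with pytest.raises(ValueError):
            classify_rhythmic(-0.1)

    @pytest.mark.parametrize(
        "rad, zt, tol",
        [(5.37, 20.51, 0.02), (0.0, 0.0, 1e-12), (math.pi, 12.0, 1e-12),
         (-math.pi, 12.0, 1e-12), (4 * math.pi, 0.0, 1e-9)],
    )
    def test_acrophase_to_zt(self, rad, zt, tol):
        assert acrophase_to_zt(rad) == pytest.approx(zt, abs=tol)

    def test_acrophase_to_zt_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            acrophase_to_zt(math.nan)


# read-only data, safe to share across hypothesis examples
@pytest.fixture(scope="module")
def dataset():
    times54 = np.repeat(np.arange(0.0, 25.0, 3.0), 6)
    rng = np.random.default_rng(9)
    return times54, _noisy(times54, 1.0, 0.4, 2.0, 0.15, rng)


class TestEquivariance:
    @given(delta=st.floats(-48, 48))
    def test_phase_equivariance(self, dataset, delta):
        """Shifting all times by delta shifts the peak ZT by delta and
        leaves M, A and P unchanged."""
        t, y = dataset
        base, shifted = fit_cosinor(t, y), fit_cosinor(t + delta, y)
        assert shifted.mesor == pytest.approx(base.mesor, abs=1e-9)
        assert shifted.amplitude == pytest.approx(base.amplitude, abs=1e-9)
        assert shifted.p_ns == pytest.approx(base.p_ns, abs=1e-9)
        diff = (shifted.acrophase_zt - base.acrophase_zt - delta) % 24
        assert min(diff, 24 - diff) == pytest.approx(0.0, abs=1e-6)

    @given(c=st.floats(1e-3, 1e3))
    def test_scale_equivariance(self, dataset, c):
        """Multiplying values by c scales M, A, SE(A) by c; P and phi
        are scale-free."""
        t, y = dataset
        base, scaled = fit_cosinor(t, y), fit_cosinor(t, c * y)
        assert scaled.mesor == pytest.approx(c * base.mesor, rel=1e-9)
        assert scaled.amplitude == pytest.approx(c * base.amplitude, rel=1e-9)
        assert scaled.se_amplitude == pytest.approx(c * base.se_amplitude, rel=1e-9)
        assert scaled.p_ns == pytest.approx(base.p_ns, rel=1e-9)
        assert scaled.acrophase_rad == pytest.approx(base.acrophase_rad, abs=1e-9)


class TestCosinorRegressor:
    def test_sklearn_protocol(self, times54):
        rng = np.random.default_rng(1)
        y = _noisy(times54, 1.0, 0.5, 2.0, 0.1, rng)
        est = CosinorRegressor(threshold=0.3)
        assert clone(est).get_params() == est.get_params()
        est.fit(times54.reshape(-1, 1), y)
        assert est.rhythmic_
        assert est.amplitude_ == pytest.approx(0.5, rel=0.2)
        pred = est.predict(times54.reshape(-1, 1))
        assert pred.shape == y.shape
        # fitted curve explains most of the variance of a strong rhythm
        assert est.score(times54.reshape(-1, 1), y) > 0.5

    def test_rejects_multicolumn_input(self, times9):
        with pytest.raises(ValueError):
            CosinorRegressor().fit(np.column_stack([times9, times9]), times9)


class TestRhythmTable:
    def test_ground_truth_panel_classification(self, design):
        """10 strongly rhythmic + 5 flat genes: exactly the 10 flagged."""
        rhythmic = [
            GeneSpec(f"r{i}", 1.0, 0.45, i * 0.6, noise_sd=0.08) for i in range(10)
        ]
        flat = [GeneSpec(f"f{i}", 1.0, 0.0, 0.0, noise_sd=0.08) for i in range(5)]
        expr = generate_expression_dataset(rhythmic + flat, design)
        table = rhythm_table(expr)
        flagged = set(table.loc[table["rhythmic"], "gene"])
        assert flagged == {f"r{i}" for i in range(10)}

    def test_flat_panel_rarely_flagged(self):
        """The P<0.3 rule is permissive but flat genes should pass it
        only rarely; count false positives over seeded replicates."""
        flags = 0
        total = 0
        for seed in range(10):
            design = StudyDesign(seed=seed)
            flat = [GeneSpec(f"f{i}", 1.0, noise_sd=0.1) for i in range(10)]
            table = rhythm_table(generate_expression_dataset(flat, design))
            flags += int(table["rhythmic"].sum())
            total += len(table)
        assert flags / total < 0.10

    def test_single_noiseless_gene_row(self, design, times9):
        expr = generate_expression_dataset(
            [GeneSpec("g", 0.5, 0.3, 2.0, noise_sd=0.0)], design
        )
        row = rhythm_table(expr).iloc[0]
        assert row["mesor"] == pytest.approx(0.5, abs=1e-9)
        assert row["amplitude"] == pytest.approx(0.3, abs=1e-9)
        assert row["acrophase"] == pytest.approx(2.0, abs=1e-9)
        assert row["p_value"] == pytest.approx(0.0, abs=1e-7)
        assert row["rhythmic"]

    def test_failing_gene_flagged_not_fatal(self, design):
        expr = generate_expression_dataset([GeneSpec("ok", 1.0, 0.4, 1.0)], design)
        bad = expr[expr["zt"] == 0].assign(gene="bad")  # single phase
        table = rhythm_table(pd.concat([expr, bad], ignore_index=True))
        bad_row = table.set_index("gene").loc["bad"]
        assert not bad_row["rhythmic"] and bad_row["error"]
        assert table.set_index("gene").loc["ok", "error"] == ""

    def test_fit_on_means_agrees_for_balanced_noiseless_data(self, design, times9):
        expr = generate_expression_dataset(
            [GeneSpec("g", 0.5, 0.3, 2.0, noise_sd=0.0)], design
        )
        by_rep = rhythm_table(expr, fit_on="replicates").iloc[0]
        by_mean = rhythm_table(expr, fit_on="timepoint_means").iloc[0]
        for col in ("mesor", "amplitude", "acrophase"):
            assert by_mean[col] == pytest.approx(by_rep[col], abs=1e-9)

    def test_unknown_fit_on_rejected(self, design):
        expr = generate_expression_dataset([GeneSpec("g", 1.0)], design)
        with pytest.raises(ValueError, match="fit_on"):
            rhythm_table(expr, fit_on="profiles")

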