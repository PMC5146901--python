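"""Single-cosinor rhythmometry with a fixed 24-h period.

The model is the classical single cosinor

    f(t) = M + A * cos(omega * t - phi),        omega = pi / 12  (rad/h)

fitted by ordinary least squares on the linearised basis
{1, cos(omega t), sin(omega t)}: writing f(t) = M + beta*cos(omega t) +
gamma*sin(omega t) gives A = sqrt(beta^2 + gamma^2) and
phi = atan2(gamma, beta), so the fitted curve peaks at t = 12*phi/pi hours
after Zeitgeber time 0.

Rhythm detection follows the amplitude noise/signal statistic
P = SE(A)/A: a profile is called rhythmic when P falls strictly below a
threshold (0.3 by default). SE(A) is obtained by the delta method from
the OLS covariance of (beta, gamma).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "OMEGA",
    "CosinorFit",
    "CosinorRegressor",
    "fit_cosinor",
    "amplitude_se",
    "classify_rhythmic",
    "acrophase_to_zt",
    "rhythm_table",
]

#: Angular frequency of a 24-hour rhythm, radians per hour.
OMEGA = math.pi / 12.0

#: Amplitudes below this are treated as numerically zero (P set to +inf).
_A_EPS = 1e-12


@dataclass
class CosinorFit:
    """Result of a single-cosinor least-squares fit for one gene.

    ``p_ns`` is the noise/signal ratio SE(A)/A; the profile is flagged
    ``rhythmic`` when ``p_ns`` is strictly below ``threshold``.
    """

    gene: str | None
    mesor: float
    amplitude: float
    acrophase_rad: float
    acrophase_zt: float
    se_amplitude: float
    p_ns: float
    rhythmic: bool
    n_obs: int
    beta: float
    gamma: float
    residual_variance: float
    threshold: float = 0.3
    coef_covariance: np.ndarray = field(repr=False, default=None)

    def predict(self, t):
        """Evaluate the fitted cosine at times ``t`` (hours)."""
        t = np.asarray(t, dtype=float)
        return self.mesor + self.amplitude * np.cos(OMEGA * t - self.acrophase_rad)


def acrophase_to_zt(acrophase_rad: float) -> float:
    """Convert an acrophase in radians to Zeitgeber hours in [0, 24).

    With a 24-h period, one radian of phase corresponds to 12/pi hours.
    """
    if not np.all(np.isfinite(acrophase_rad)):
        raise ValueError("acrophase must be finite")
    return (np.asarray(acrophase_rad, dtype=float) * 12.0 / math.pi) % 24.0


def classify_rhythmic(p_ns: float, threshold: float = 0.3) -> bool:
    """Apply the strict noise/signal rule: rhythmic iff P < threshold."""
    if p_ns < 0:
        raise ValueError("p_ns must be nonnegative")
    return bool(p_ns < threshold)


def amplitude_se(fit: CosinorFit) -> float:
    """Delta-method standard error of the amplitude.

    With A = sqrt(beta^2 + gamma^2) and OLS covariance Sigma of
    (beta, gamma),

        Var(A) = (beta^2 Var(beta) + gamma^2 Var(gamma)
                  + 2 beta gamma Cov(beta, gamma)) / A^2.

    Raises for a numerically zero amplitude, where the linearisation
    degenerates; callers map that case to P = +inf.
    """
    if fit.amplitude < _A_EPS:
        raise ZeroDivisionError("amplitude is numerically zero; SE(A) undefined")
    return _amplitude_se(fit.beta, fit.gamma, fit.coef_covariance)


def _amplitude_se(beta: float, gamma: float, cov: np.ndarray) -> float:
    a2 = beta * beta + gamma * gamma
    var_a = (
        beta * beta * cov[1, 1]
        + gamma * gamma * cov[2, 2]
        + 2.0 * beta * gamma * cov[1, 2]
    ) / a2
    # roundoff can push a zero-residual variance slightly negative
    return math.sqrt(max(var_a, 0.0))


def fit_cosinor(
    times, values, threshold: float = 0.3, gene: str | None = None
) -> CosinorFit:
    """Fit the 24-h single cosinor by OLS and score rhythmicity.

    Parameters
    ----------
    times : array-like of float
        Sampling times in Zeitgeber hours. ZT0 and ZT24 are distinct
        observations at the same phase.
    values : array-like of float
        Expression levels, one per time.
    threshold : float
        Noise/signal cutoff for the rhythmic flag (strict inequality).
    gene : str, optional
        Label carried into the result.

    Requires at least 4 observations spanning >= 3 distinct phases
    (times mod 24); otherwise the three-parameter model is unidentifiable.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("times and values must be equal-length 1-d arrays")
    n = t.size
    if n < 4:
        raise ValueError(f"need at least 4 observations, got {n}")
    phases = np.unique(np.round(np.mod(t, 24.0), 9))
    if phases.size < 3:
        raise ValueError(
            f"degenerate design: only {phases.size} distinct phase(s); need >= 3"
        )

    X = np.column_stack([np.ones(n), np.cos(OMEGA * t), np.sin(OMEGA * t)])
    xtx = X.T @ X
    coef = np.linalg.solve(xtx, X.T @ y)
    mesor, beta, gamma = coef
    resid = y - X @ coef
    rss = float(resid @ resid)
    residual_variance = rss / (n - 3)
    cov = residual_variance * np.linalg.inv(xtx)

    amplitude = math.hypot(beta, gamma)
    acrophase = math.atan2(gamma, beta) % (2.0 * math.pi)
    if 2.0 * math.pi - acrophase < 1e-9:  # roundoff just below the wrap point
        acrophase = 0.0

    if amplitude < _A_EPS:
        se_a, p_ns = 0.0, math.inf
    else:
        se_a = _amplitude_se(beta, gamma, cov)
        p_ns = se_a / amplitude

    return CosinorFit(
        gene=gene,
        mesor=float(mesor),
        amplitude=float(amplitude),
        acrophase_rad=float(acrophase),
        acrophase_zt=float(acrophase_to_zt(acrophase)),
        se_amplitude=float(se_a),
        p_ns=float(p_ns),
        rhythmic=classify_rhythmic(p_ns, threshold) if math.isfinite(p_ns) else False,
        n_obs=int(n),
        beta=float(beta),
        gamma=float(gamma),
        residual_variance=float(residual_variance),
        threshold=float(threshold),
        coef_covariance=cov,
    )


class CosinorRegressor(RegressorMixin, BaseEstimator):
    """Scikit-learn style estimator for the fixed-period single cosinor.

    ``fit(X, y)`` takes times in hours (1-d array or single-column 2-d
    array) and expression values; ``predict(X)`` evaluates the fitted
    curve. Fitted attributes mirror :class:`CosinorFit`.

    Parameters
    ----------
    threshold : float, default 0.3
        Strict cutoff on the noise/signal statistic P = SE(A)/A below
        which the series is flagged rhythmic.
    """

    def __init__(self, threshold: float = 0.3):
        self.threshold = threshold

    @staticmethod
    def _as_times(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("X must have a single column of times")
            X = X[:, 0]
        return X

    def fit(self, X, y):
        t = self._as_times(X)
        fit = fit_cosinor(t, y, threshold=self.threshold)
        self.mesor_ = fit.mesor
        self.amplitude_ = fit.amplitude
        self.acrophase_rad_ = fit.acrophase_rad
        self.acrophase_zt_ = fit.acrophase_zt
        self.se_amplitude_ = fit.se_amplitude
        self.p_ns_ = fit.p_ns
        self.rhythmic_ = fit.rhythmic
        self.beta_ = fit.beta
        self.gamma_ = fit.gamma
        self.residual_variance_ = fit.residual_variance
        self.n_obs_ = fit.n_obs
        self.coef_ = np.array([fit.mesor, fit.beta, fit.gamma])
        self.result_ = fit
        return self

    def predict(self, X):
        check_is_fitted(self, "result_")
        return self.result_.predict(self._as_times(X))


def rhythm_table(
    expr: pd.DataFrame,
    genes=None,
    fit_on: str = "replicates",
    threshold: float = 0.3,
) -> pd.DataFrame:
    """Per-gene cosinor summary table (amplitude, P, mesor, acrophase, ZT).

    Parameters
    ----------
    expr : DataFrame
        Long-format relative expression with columns
        (sample_id, gene, zt, replicate, value).
    genes : iterable of str, optional
        Genes to fit, in output order; defaults to first-appearance order.
    fit_on : {"replicates", "timepoint_means"}
        Fit on all replicate observations, or collapse to per-ZT means
        first (the two defensible readings of a means-plot cosinor).
    threshold : float
        Noise/signal cutoff for the rhythmic flag.

    A gene whose fit fails (too few points, degenerate phases) yields a
    row of NaNs with ``rhythmic=False`` and the error message in
    ``error``; the batch never aborts.
    """
    if fit_on not in ("replicates", "timepoint_means"):
        raise ValueError(f"unknown fit_on: {fit_on!r}")
    if genes is None:
        genes = list(dict.fromkeys(expr["gene"]))
    rows = []
    for gene in genes:
        sub = expr.loc[expr["gene"] == gene]
        if fit_on == "timepoint_means":
            sub = sub.groupby("zt", as_index=False)["value"].mean()
        try:
            if sub.empty:
                raise ValueError(f"no data for gene {gene!r}")
            fit = fit_cosinor(sub["zt"], sub["value"], threshold=threshold, gene=gene)
            rows.append(
                dict(
                    gene=gene,
                    amplitude=fit.amplitude,
                    p_value=fit.p_ns,
                    mesor=fit.mesor,
                    acrophase=fit.acrophase_rad,
                    zt_h=fit.acrophase_zt,
                    rhythmic=fit.rhythmic,
                    error="",
                )
            )
        except ValueError as exc:
            rows.append(
                dict(
                    gene=gene,
                    amplitude=np.nan,
                    p_value=np.nan,
                    mesor=np.nan,
                    acrophase=np.nan,
                    zt_h=np.nan,
                    rhythmic=False,
                    error=str(exc),
                )
            )
    return pd.DataFrame(rows)
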