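"""Single- and multi-component cosinor regression with a fixed 24-h period.

The model fitted here is trigonometric least squares,

    Y(t) = M + sum_i A_i cos(2*pi*i*t/24 + phi_i) + e(t),

where ``M`` is the MESOR (rhythm-adjusted mean), ``A_i >= 0`` the amplitude of
harmonic ``i`` and ``phi_i`` its acrophase in radians.  Writing each component
as ``beta_i cos(w_i t) + gamma_i sin(w_i t)`` turns the fit into ordinary least
squares on the regressors ``{1, cos, sin}``; amplitudes and acrophases are
recovered through

    A_i = sqrt(beta_i**2 + gamma_i**2),   phi_i = atan2(-gamma_i, beta_i).

Sign convention (fixed here once, for the whole package): acrophases live on
the principal branch ``(-pi, pi]`` and the fitted cosine peaks at clock time
``t = -phi * 24 / (2*pi) (mod 24)``.  Every other module converts through
:func:`acrophase_to_peak_hour` so the convention cannot drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

PERIOD_HOURS = 24.0
OMEGA = 2.0 * np.pi / PERIOD_HOURS

__all__ = [
    "CosinorFit",
    "FitError",
    "fit_cosinor",
    "zero_amplitude_test",
    "select_components",
    "acrophase_to_peak_hour",
    "peak_hour_to_acrophase",
    "wrap_angle",
    "params_from_coefficients",
    "evaluate_curve",
]


class FitError(ValueError):
    """Raised when a cosinor fit is impossible (rank deficiency, too few points)."""


def wrap_angle(phi):
    """Wrap angles to the principal branch (-pi, pi]."""
    phi = np.asarray(phi, dtype=float)
    wrapped = phi - 2.0 * np.pi * np.floor((phi + np.pi) / (2.0 * np.pi))
    # floor maps x == pi (mod 2pi) to -pi; the convention here keeps +pi
    wrapped = np.where(np.isclose(wrapped, -np.pi), np.pi, wrapped)
    if wrapped.ndim == 0:
        return float(wrapped)
    return wrapped


def acrophase_to_peak_hour(phi: float) -> float:
    """Clock hour in [0, 24) at which ``cos(2*pi*t/24 + phi)`` peaks."""
    if not np.isfinite(phi):
        raise ValueError("acrophase must be finite")
    return float((-phi / OMEGA) % PERIOD_HOURS)


def peak_hour_to_acrophase(hour: float) -> float:
    """Inverse of :func:`acrophase_to_peak_hour`, on the principal branch."""
    return float(wrap_angle(-float(hour) * OMEGA))


def _design_matrix(t: np.ndarray, n_components: int) -> np.ndarray:
    cols = [np.ones_like(t)]
    for i in range(1, n_components + 1):
        cols.append(np.cos(i * OMEGA * t))
        cols.append(np.sin(i * OMEGA * t))
    return np.column_stack(cols)


@dataclass
class CosinorFit:
    """Result of one cosinor regression.

    ``coefficients`` is the linear coefficient vector
    ``[M, beta_1, gamma_1, ..., beta_N, gamma_N]``; ``amplitudes`` and
    ``acrophases`` are derived from it.  ``p_zero_amplitude`` is the
    zero-amplitude F-test p value (H0: no rhythm, all beta/gamma zero).
    """

    coefficients: np.ndarray
    n_components: int
    n_obs: int
    rss: float
    rss_intercept: float
    t: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    degenerate: bool = False
    period: float = PERIOD_HOURS

    @property
    def mesor(self) -> float:
        return float(self.coefficients[0])

    @property
    def betas(self) -> np.ndarray:
        return self.coefficients[1::2]

    @property
    def gammas(self) -> np.ndarray:
        return self.coefficients[2::2]

    @property
    def amplitudes(self) -> np.ndarray:
        return np.hypot(self.betas, self.gammas)

    @property
    def acrophases(self) -> np.ndarray:
        return np.atleast_1d(wrap_angle(np.arctan2(-self.gammas, self.betas)))

    @property
    def amplitude(self) -> float:
        """Overall amplitude: A_1 for N=1, else (max-min)/2 of the fitted curve."""
        return params_from_coefficients(self.coefficients)[1]

    @property
    def acrophase(self) -> float:
        return params_from_coefficients(self.coefficients)[2]

    @property
    def peak_hour(self) -> float:
        return params_from_coefficients(self.coefficients)[3]

    @property
    def df_resid(self) -> int:
        return self.n_obs - (2 * self.n_components + 1)

    @property
    def residual_se(self) -> float:
        return float(np.sqrt(self.rss / self.df_resid))

    @property
    def p_zero_amplitude(self) -> float:
        return zero_amplitude_test(self)

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return _design_matrix(t, self.n_components) @ self.coefficients

    @property
    def residuals(self) -> np.ndarray:
        return self.y - self.predict(self.t)


def fit_cosinor(t, y, n_components: int = 1) -> CosinorFit:
    """Least-squares cosinor fit with ``n_components`` harmonics of 24 h.

    Parameters
    ----------
    t : array-like
        Sampling times in hours (clock time; any finite values, used mod 24
        implicitly through the trigonometric regressors).
    y : array-like
        Observed values, same length as ``t``.
    n_components : int
        Number of cosine harmonics N (angular frequencies ``2*pi*i/24``).

    Raises
    ------
    FitError
        If there are fewer than ``2N + 2`` observations or the design matrix
        is rank deficient (e.g. all times identical).
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    t = np.asarray(t, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if t.shape != y.shape:
        raise ValueError("t and y must have the same length")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise ValueError("t and y must be finite")
    n = t.size
    n_params = 2 * n_components + 1
    if n < n_params + 1:
        raise FitError(
            f"need at least {n_params + 1} observations for N={n_components}, got {n}"
        )
    X = _design_matrix(t, n_components)
    if np.linalg.matrix_rank(X) < n_params:
        raise FitError("rank-deficient design (degenerate sampling times)")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    rss0 = float(np.sum((y - y.mean()) ** 2))
    # a perfect rhythmic fit (RSS ~ 0 with real variance) is flagged; a
    # constant series (RSS0 ~ 0) is not a rhythm at all
    degenerate = rss0 > 0.0 and rss <= 1e-12 * rss0
    return CosinorFit(
        coefficients=coef,
        n_components=n_components,
        n_obs=n,
        rss=rss,
        rss_intercept=rss0,
        t=t,
        y=y,
        degenerate=degenerate,
    )


def zero_amplitude_test(fit: CosinorFit) -> float:
    """Zero-amplitude F-test p value for a fitted cosinor model.

    Compares the full fit against the intercept-only model:
    ``F = ((RSS0 - RSS) / 2N) / (RSS / (n - 2N - 1))`` with an
    ``F(2N, n - 2N - 1)`` reference distribution.  A numerically perfect fit
    (RSS ~ 0) returns ``p = 0`` and is flagged via ``fit.degenerate``.
    """
    if fit.df_resid <= 0:
        raise FitError("no residual degrees of freedom for the zero-amplitude test")
    if fit.rss_intercept <= 0.0:
        return 1.0  # constant series: no variance, no rhythm
    if fit.degenerate:
        return 0.0
    df_num = 2 * fit.n_components
    f_stat = ((fit.rss_intercept - fit.rss) / df_num) / (fit.rss / fit.df_resid)
    return float(stats.f.sf(f_stat, df_num, fit.df_resid))


def select_components(t, y, max_components: int = 3, alpha: float = 0.05) -> CosinorFit:
    """Pick the number of harmonics by the extra sum-of-squares F-test.

    Starts from N=1 and steps to N+1 only when the nested comparison
    ``F = ((RSS_N - RSS_{N+1}) / 2) / (RSS_{N+1} / df_{N+1})`` is significant
    at ``alpha``; ties and non-significant improvements resolve toward the
    smaller model.  Candidates whose sample size is too small are skipped.
    """
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    current = fit_cosinor(t, y, 1)
    for n_next in range(2, max_components + 1):
        if current.rss <= 1e-12 * max(current.rss_intercept, 1.0):
            break  # smaller model already (numerically) perfect
        n = current.n_obs
        if n < 2 * n_next + 2:
            break
        bigger = fit_cosinor(t, y, n_next)
        df_big = bigger.df_resid
        if bigger.rss <= 1e-12 * max(bigger.rss_intercept, 1.0):
            p_extra = 0.0
        else:
            f_stat = ((current.rss - bigger.rss) / 2.0) / (bigger.rss / df_big)
            p_extra = float(stats.f.sf(f_stat, 2, df_big))
        if p_extra < alpha:
            current = bigger
        else:
            break
    return current


def evaluate_curve(coefficients, t) -> np.ndarray:
    """Evaluate the cosinor curve with the given coefficient vector at hours t."""
    coefficients = np.asarray(coefficients, dtype=float)
    n_components = (coefficients.size - 1) // 2
    t = np.asarray(t, dtype=float)
    return _design_matrix(t, n_components) @ coefficients


def params_from_coefficients(coefficients):
    """Derive (mesor, amplitude, acrophase, peak_hour) from a coefficient vector.

    For a single harmonic these are the exact closed-form parameters.  For
    multi-component curves the summary follows the fitted curve's shape:
    peak hour is the argmax on a 1-minute grid and amplitude is half the
    peak-to-trough range, with the acrophase defined as the phase whose peak
    lies at that hour.
    """
    coefficients = np.asarray(coefficients, dtype=float)
    mesor = float(coefficients[0])
    n_components = (coefficients.size - 1) // 2
    if n_components == 1:
        beta, gamma = coefficients[1], coefficients[2]
        amplitude = float(np.hypot(beta, gamma))
        acrophase = float(wrap_angle(np.arctan2(-gamma, beta)))
        peak = acrophase_to_peak_hour(acrophase) if amplitude > 0 else 0.0
        return mesor, amplitude, acrophase, peak
    grid = np.arange(0.0, PERIOD_HOURS, 1.0 / 60.0)
    curve = evaluate_curve(coefficients, grid)
    amplitude = float((curve.max() - curve.min()) / 2.0)
    peak = float(grid[int(np.argmax(curve))])
    acrophase = peak_hour_to_acrophase(peak)
    return mesor, amplitude, acrophase, peak
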