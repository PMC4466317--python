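"""Hurst-exponent estimation: nine estimator modes behind one model object.

The Hurst exponent H quantifies long-range dependence of a stationary
series: H = 0.5 for a memoryless series, H > 0.5 for persistent
(long-range correlated) behaviour, H < 0.5 for anti-persistence.  For a
long-memory process the autocovariance decays as gamma(k) ~ k^(2H-2) and
the spectral density diverges at the origin as f^(1-2H); every estimator
here exploits one of those power laws.

The modes (six families, nine modes) are:

=================  ==========================================================
``rs``             rescaled-range (R/S) analysis
``spec_standard``  log-periodogram regression over the lowest frequencies
``spec_smoothed``  same, on a moving-average-smoothed periodogram
``spec_robinson``  Robinson-type local-Whittle semiparametric estimate
``acvf``           autocovariance-decay fit in asinh scale vs log(lag)
``dfa``            detrended fluctuation analysis
``whittle``        full-band Whittle fit of a fractionally differenced model
``block_aggvar``   aggregated-variance (block means) regression
``block_higuchi``  Higuchi curve-length (fractal dimension) method
=================  ==========================================================

Estimates are deliberately NOT clipped to [0.5, 1]: anti-persistent values
below 0.5, and small excursions above 1, are reported as-is so that the
downstream distributional analysis is not distorted.

The model/results interface follows the statsmodels convention::

    res = HurstModel(series, method="dfa").fit()
    res.H, res.slope, res.rsquared
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .codec import DigitizedSequence
from .exceptions import (
    DegenerateSeriesError,
    EstimationError,
    SeriesTooShortError,
)

METHODS = (
    "rs",
    "spec_standard",
    "spec_smoothed",
    "spec_robinson",
    "acvf",
    "dfa",
    "whittle",
    "block_aggvar",
    "block_higuchi",
)

#: minimum series length accepted by every estimator
MIN_SERIES_LENGTH = 64

#: smallest scale of the log-spaced grid, per method.  R/S needs larger
#: blocks than the others: the small-block rescaled range is biased upward
#: (the Anis-Lloyd finite-sample effect), so its grid starts at 16.
_DEFAULT_MIN_SCALE = {
    "rs": 16,
    "dfa": 8,
    "block_aggvar": 4,
    "block_higuchi": 4,
}

#: largest scale as a fraction of the series length, per method.  The block
#: estimators (aggregated variance, Higuchi) lose accuracy when blocks get
#: close to the series length — block means become strongly correlated and
#: the statistics at the largest scales are systematically low — so their
#: grids stop at N/16 while the regression-profile methods use N/4.
_DEFAULT_MAX_SCALE_FRACTION = {
    "block_aggvar": 0.0625,
    "block_higuchi": 0.0625,
}

#: absolute tolerance of the bounded scalar minimizations (whittle,
#: robinson, acvf); deterministic, no random restarts
_OPT_XATOL = 1e-6


@dataclass(frozen=True)
class EstimatorConfig:
    """Tuning parameters shared by the nine estimator modes.

    Parameters
    ----------
    min_scale
        Smallest block size / lag of the log-spaced grid.  ``None`` selects
        a per-method default (16 for ``rs``, 8 for ``dfa``, 4 otherwise).
    max_scale_fraction
        Largest scale as a fraction of the series length.  ``None`` selects
        a per-method default (1/16 for the block modes, 1/4 otherwise).
    n_scales
        Number of log-spaced scales requested (deduplicated after integer
        rounding, so fewer may be used).
    dfa_order
        Order of the detrending polynomial in DFA.
    spec_cutoff_fraction
        Fraction of the lowest Fourier frequencies used by the spectral
        regressions.
    spec_smooth_span
        Odd moving-average span applied to the periodogram in
        ``spec_smoothed`` mode.
    robinson_power
        Bandwidth exponent of the local-Whittle estimate: m = floor(N^power)
        frequencies enter the objective.
    acvf_max_lag_fraction
        Largest autocovariance lag as a fraction of the series length.
    """

    min_scale: int | None = None
    max_scale_fraction: float | None = None
    n_scales: int = 16
    dfa_order: int = 1
    spec_cutoff_fraction: float = 0.125
    spec_smooth_span: int = 7
    robinson_power: float = 0.65
    acvf_max_lag_fraction: float = 0.125

    def __post_init__(self):
        if self.min_scale is not None and self.min_scale < 4:
            raise ValueError("min_scale must be >= 4")
        if self.max_scale_fraction is not None and not 0 < self.max_scale_fraction <= 1:
            raise ValueError("max_scale_fraction must be in (0, 1]")
        if self.n_scales < 4:
            raise ValueError("n_scales must be >= 4")
        if self.dfa_order < 1:
            raise ValueError("dfa_order must be >= 1")
        if not 0 < self.spec_cutoff_fraction <= 0.5:
            raise ValueError("spec_cutoff_fraction must be in (0, 0.5]")
        if self.spec_smooth_span < 3 or self.spec_smooth_span % 2 == 0:
            raise ValueError("spec_smooth_span must be an odd integer >= 3")
        if not 0 < self.robinson_power < 1:
            raise ValueError("robinson_power must be in (0, 1)")
        if not 0 < self.acvf_max_lag_fraction <= 0.5:
            raise ValueError("acvf_max_lag_fraction must be in (0, 0.5]")

    def resolved_min_scale(self, method: str) -> int:
        if self.min_scale is not None:
            return self.min_scale
        return _DEFAULT_MIN_SCALE.get(method, 4)

    def resolved_max_scale_fraction(self, method: str) -> float:
        if self.max_scale_fraction is not None:
            return self.max_scale_fraction
        return _DEFAULT_MAX_SCALE_FRACTION.get(method, 0.25)


DEFAULT_CONFIG = EstimatorConfig()


@dataclass(frozen=True)
class HurstResults:
    """Result of one estimator mode.

    ``slope``/``intercept``/``rsquared`` carry the log-log regression
    evidence; for the likelihood-type modes (``whittle``, ``spec_robinson``)
    they are ``None`` (not applicable).  ``scales`` holds the block sizes,
    lags or frequencies actually used and ``statistics`` the per-scale
    quantities (mean R/S, fluctuation, variance, curve length, periodogram
    ordinate, or asinh-scaled autocovariance).
    """

    method: str
    H: float
    slope: float | None
    intercept: float | None
    scales: np.ndarray
    statistics: np.ndarray
    rsquared: float | None

    @property
    def n_points(self) -> int:
        return int(len(self.scales))

    def summary(self) -> str:
        lines = [
            "Hurst exponent estimate",
            "=" * 39,
            f"method:        {self.method}",
            f"H:             {self.H:.6f}",
            f"n_points:      {self.n_points}",
        ]
        if self.slope is not None:
            lines.append(f"slope:         {self.slope:.6f}")
            lines.append(f"intercept:     {self.intercept:.6f}")
        if self.rsquared is not None:
            lines.append(f"R-squared:     {self.rsquared:.6f}")
        lines.append("=" * 39)
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# shared helpers


def _as_series(series) -> np.ndarray:
    if isinstance(series, DigitizedSequence):
        series = series.values
    x = np.asarray(series, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    return x


def _prepare(series) -> np.ndarray:
    """Validate, mean-center and scale-normalize the input series.

    All modes operate on the standardized series, which makes every
    estimate exactly invariant under shifts and positive rescalings of the
    input.
    """
    x = _as_series(series)
    n = x.size
    if n < MIN_SERIES_LENGTH:
        raise SeriesTooShortError(
            f"series length {n} below minimum {MIN_SERIES_LENGTH}"
        )
    sd = float(np.std(x))
    if sd == 0.0:
        raise DegenerateSeriesError("series is constant; no Hurst exponent")
    return (x - float(np.mean(x))) / sd


def loglog_fit(scales, statistics) -> tuple[float, float, float]:
    """Least-squares line through (log scales, log statistics).

    Returns (slope, intercept, r_squared).  This is the shared regression
    core of the scale-based modes.
    """
    lx = np.log(np.asarray(scales, dtype=float))
    ly = np.log(np.asarray(statistics, dtype=float))
    return linear_fit(lx, ly)


def linear_fit(x, y) -> tuple[float, float, float]:
    """Ordinary least squares y = a*x + b via the normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise SeriesTooShortError("need at least 2 points for a line fit")
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    sxy = float(np.sum((x - xm) * (y - ym)))
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - (slope * x + intercept)
    syy = float(np.sum((y - ym) ** 2))
    r2 = 1.0 if syy == 0 else 1.0 - float(np.sum(resid**2)) / syy
    return slope, intercept, max(min(r2, 1.0), 0.0)


def scale_grid(n: int, method: str, config: EstimatorConfig) -> np.ndarray:
    """Log-spaced integer scale grid for a series of length ``n``."""
    lo = config.resolved_min_scale(method)
    hi = int(np.floor(n * config.resolved_max_scale_fraction(method)))
    if hi <= lo:
        raise SeriesTooShortError(
            f"series length {n} leaves no scales in [{lo}, {hi}] for {method}"
        )
    grid = np.unique(
        np.round(np.geomspace(lo, hi, config.n_scales)).astype(int)
    )
    if grid.size < 4:
        raise SeriesTooShortError(
            f"only {grid.size} distinct scales for length {n}; need >= 4"
        )
    return grid


def _periodogram(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Periodogram I(f_j) = |FFT|^2 / N at Fourier frequencies j/N."""
    n = x.size
    spec = np.abs(np.fft.rfft(x)) ** 2 / n
    j = np.arange(1, n // 2 + 1)
    return j / n, spec[1 : n // 2 + 1]


def _autocovariance(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased sample autocovariance gamma(0..max_lag) via FFT."""
    n = x.size
    xc = x - x.mean()
    m = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, m)
    acov = np.fft.irfft(f * np.conj(f), m)[: max_lag + 1].real / n
    return acov


def fgn_autocorrelation(H: float, lags: np.ndarray) -> np.ndarray:
    """Exact fractional-Gaussian-noise autocorrelation at the given lags."""
    k = np.asarray(lags, dtype=float)
    return 0.5 * (
        np.abs(k + 1) ** (2 * H) - 2 * np.abs(k) ** (2 * H) + np.abs(k - 1) ** (2 * H)
    )


# ---------------------------------------------------------------------------
# the nine modes


def _fit_rs(x: np.ndarray, config: EstimatorConfig) -> HurstResults:
    n = x.size
    grid = scale_grid(n, "rs", config)
    scales, stats = [], []
    for m in grid:
        nb = n // m
        segs = x[: nb * m].reshape(nb, m)
        dev = segs - segs.mean(axis=1, keepdims=True)
        z = np.cumsum(dev, axis=1)
        rng = z.max(axis=1) - z.min(axis=1)
        sd = segs.std(axis=1)
        ok = sd > 0
        if not ok.any():
            continue  # all blocks constant at this scale: drop the scale
        scales.append(m)
        stats.append(float(np.mean(rng[ok] / sd[ok])))
    if len(scales) < 4:
        raise SeriesTooShortError("fewer than 4 usable R/S scales")
    slope, intercept, r2 = loglog_fit(scales, stats)
    return HurstResults(
        "rs", slope, slope, intercept, np.asarray(scales), np.asarray(stats), r2
    )


def _fit_dfa(x: np.ndarray, config: EstimatorConfig) -> HurstResults:
    n = x.size
    profile = np.cumsum(x)
    grid = scale_grid(n, "dfa", config)
    order = config.dfa_order
    flucts = []
    for m in grid:
        nb = n // m
        segs = profile[: nb * m].reshape(nb, m).T  # (m, nb)
        design = np.vander(np.arange(m, dtype=float), order + 1)
        coef, *_ = np.linalg.lstsq(design, segs, rcond=None)
        resid = segs - design @ coef
        flucts.append(float(np.sqrt(np.mean(resid**2))))
    slope, intercept, r2 = loglog_fit(grid, flucts)
    return HurstResults(
        "dfa", slope, slope, intercept, grid, np.asarray(flucts), r2
    )


def _spectral_regression(
    x: np.ndarray, config: EstimatorConfig, smoothed: bool
) -> tuple[float, float, np.ndarray, np.ndarray, float]:
    freqs, spec = _periodogram(x)
    if smoothed:
        span = config.spec_smooth_span
        kernel = np.ones(span)
        counts = np.convolve(np.ones_like(spec), kernel, mode="same")
        spec = np.convolve(spec, kernel, mode="same") / counts
    m = max(4, int(np.floor(freqs.size * config.spec_cutoff_fraction)))
    f, s = freqs[:m], spec[:m]
    keep = s > 0
    slope, intercept, r2 = loglog_fit(f[keep], s[keep])
    return slope, intercept, f[keep], s[keep], r2


def _fit_spec_standard(x: np.ndarray, config: EstimatorConfig) -> HurstResults:
    slope, intercept, f, s, r2 = _spectral_regression(x, config, smoothed=False)
    return HurstResults("spec_standard", (1.0 - slope) / 2.0, slope, intercept, f, s, r2)


def _fit_spec_smoothed(x: np.ndarray, config: EstimatorConfig) -> HurstResults:
    slope, intercept, f, s, r2 = _spectral_regression(x, config, smoothed=True)
    return HurstResults("spec_smoothed", (1.0 - slope) / 2.0, slope, intercept, f, s, r2)


def _fit_spec_robinson(x: np.ndarray, config: EstimatorConfig) -> HurstResults:
    freqs, spec = _periodogram(x)
    n = x.size
    m = min(int(np.floor(n**config.robinson_power)), freqs.size)
    f, s = freqs[:m], spec[:m]
    mean_logf = float(np.mean(np.log(f)))

    def objective(h: float) -> float:
        return float(
            np.log(np.mean(s * f ** (2 * h - 1))) - (2 * h - 1) * mean_logf
        )

    res = minimize_scalar(
        objective, bounds=(0.01, 1.49), method="bounded",
        options={"xatol": _OPT_XATOL},
    )
    return HurstResults("spec_robinson", float(res.x), None, None, f, s, None)


def fgn_spectral_shape(f: np.ndarray, H: float, n_terms: int = 10) -> np.ndarray:
    """Spectral density of fGn up to a constant factor.

    S(f) proportional to (1 - cos 2 pi f) * sum_{j in Z} |f + j|^(-2H-1);
    the aliasing sum is truncated at ``n_terms`` with an integral tail
    correction, which is accurate to well below periodogram noise.
    """
    d = -(2.0 * H + 1.0)
    total = np.abs(f) ** d
    for j in range(1, n_terms + 1):
        total = total + (j + f) ** d + (j - f) ** d
    edge = n_terms + 0.5
    total = total + ((edge + f) ** (d + 1) + (edge - f) ** (d + 1)) / (2.0 * H)
    return (1.0 - np.cos(2.0 * np.pi * f)) * total


def _fit_whittle(x: np.ndarray, config: EstimatorConfig) -> HurstResults:
    freqs, spec = _periodogram(x)
    n = x.size
    # exclude the Nyquist ordinate: j = 1 .. N/2 - 1
    f, s = freqs[: n // 2 - 1], spec[: n // 2 - 1]

    def objective(h: float) -> float:
        # scale profiled out: shape normalized to unit geometric mean
        log_g = np.log(fgn_spectral_shape(f, h))
        log_g -= log_g.mean()
        return float(np.mean(s * np.exp(-log_g)))

    res = minimize_scalar(
        objective, bounds=(0.01, 0.99), method="bounded",
        options={"xatol": _OPT_XATOL},
    )
    return HurstResults("whittle", float(res.x), None, None, f, s, None)


def _fit_acvf(x: np.ndarray, config: EstimatorConfig) -> HurstResults:
    n = x.size
    max_lag = max(4, int(np.floor(n * config.acvf_max_lag_fraction)))
    acov = _autocovariance(x, max_lag)
    lags = np.arange(1, max_lag + 1)
    stat = np.arcsinh(acov[1:] / (2.0 * acov[0]))

    def objective(h: float) -> float:
        model = np.arcsinh(fgn_autocorrelation(h, lags) / 2.0)
        return float(np.sum((stat - model) ** 2))

    res = minimize_scalar(
        objective, bounds=(0.01, 0.999), method="bounded",
        options={"xatol": _OPT_XATOL},
    )
    h = float(res.x)
    # diagnostic straight line through the asinh-vs-log(lag) plot
    slope, intercept, r2 = linear_fit(np.log(lags), stat)
    return HurstResults("acvf", h, slope, intercept, lags, stat, r2)


def _fit_block_aggvar(x: np.ndarray, config: EstimatorConfig) -> HurstResults:
    n = x.size
    grid = scale_grid(n, "block_aggvar", config)
    scales, stats = [], []
    for m in grid:
        nb = n // m
        if nb < 2:
            continue
        means = x[: nb * m].reshape(nb, m).mean(axis=1)
        v = float(np.var(means, ddof=1))
        if v <= 0:
            continue
        scales.append(m)
        stats.append(v)
    if len(scales) < 4:
        raise SeriesTooShortError("fewer than 4 usable aggregated-variance scales")
    slope, intercept, r2 = loglog_fit(scales, stats)
    return HurstResults(
        "block_aggvar", 1.0 + slope / 2.0, slope, intercept,
        np.asarray(scales), np.asarray(stats), r2,
    )


def _fit_block_higuchi(x: np.ndarray, config: EstimatorConfig) -> HurstResults:
    n = x.size
    profile = np.cumsum(x)
    grid = scale_grid(n, "block_higuchi", config)
    lengths = []
    for k in grid:
        d = np.abs(profile[k:] - profile[:-k])  # d[j] = |Y(j+k) - Y(j)|
        offsets = np.arange(1, k + 1)
        m_o = (n - offsets) // k  # terms per offset
        sums = np.bincount(np.arange(d.size) % k, weights=d, minlength=k)
        per_offset = (n - 1) / (m_o * k * k) * sums
        lengths.append(float(np.mean(per_offset)))
    slope, intercept, r2 = loglog_fit(grid, lengths)
    # slope = -D (curve dimension); H = 2 - D
    return HurstResults(
        "block_higuchi", 2.0 + slope, slope, intercept, grid, np.asarray(lengths), r2
    )


_FITTERS = {
    "rs": _fit_rs,
    "spec_standard": _fit_spec_standard,
    "spec_smoothed": _fit_spec_smoothed,
    "spec_robinson": _fit_spec_robinson,
    "acvf": _fit_acvf,
    "dfa": _fit_dfa,
    "whittle": _fit_whittle,
    "block_aggvar": _fit_block_aggvar,
    "block_higuchi": _fit_block_higuchi,
}


class HurstModel:
    """Long-memory scaling model for a single series.

    Parameters
    ----------
    series : array-like or DigitizedSequence
        The input series (a digitized gene, an fGn realization, ...).
    method : str
        One of :data:`METHODS`.
    config : EstimatorConfig, optional
        Tuning parameters; defaults are conventional choices.
    """

    def __init__(self, series, method: str = "spec_smoothed",
                 config: EstimatorConfig | None = None):
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
        self.series = series
        self.method = method
        self.config = config or DEFAULT_CONFIG

    def fit(self) -> HurstResults:
        x = _prepare(self.series)
        return _FITTERS[self.method](x, self.config)


def estimate(series, method: str = "spec_smoothed",
             config: EstimatorConfig | None = None) -> HurstResults:
    """One-call convenience wrapper around :class:`HurstModel`."""
    return HurstModel(series, method=method, config=config).fit()


def estimate_rs(series, config: EstimatorConfig | None = None) -> HurstResults:
    return estimate(series, "rs", config)


def estimate_spectral(series, mode: str = "standard",
                      config: EstimatorConfig | None = None) -> HurstResults:
    if mode not in ("standard", "smoothed", "robinson"):
        raise ValueError("mode must be 'standard', 'smoothed' or 'robinson'")
    return estimate(series, f"spec_{mode}", config)


def estimate_acvf(series, config: EstimatorConfig | None = None) -> HurstResults:
    return estimate(series, "acvf", config)


def estimate_dfa(series, config: EstimatorConfig | None = None) -> HurstResults:
    return estimate(series, "dfa", config)


def estimate_whittle(series, config: EstimatorConfig | None = None) -> HurstResults:
    return estimate(series, "whittle", config)


def estimate_block(series, mode: str = "aggvar",
                   config: EstimatorConfig | None = None) -> HurstResults:
    if mode not in ("aggvar", "higuchi"):
        raise ValueError("mode must be 'aggvar' or 'higuchi'")
    return estimate(series, f"block_{mode}", config)


def estimate_all(
    series,
    configs: Mapping[str, EstimatorConfig] | None = None,
    methods: Sequence[str] = METHODS,
) -> tuple[dict[str, HurstResults], dict[str, str]]:
    """Run several estimator modes on one series.

    Returns ``(estimates, failures)``: per-method results, and per-method
    error messages for modes that failed.  Raises EstimationError only if
    every requested mode fails.
    """
    configs = configs or {}
    estimates: dict[str, HurstResults] = {}
    failures: dict[str, str] = {}
    for method in methods:
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}")
        try:
            estimates[method] = estimate(series, method, configs.get(method))
        except Exception as exc:  # per-method failures must not abort the rest
            failures[method] = f"{type(exc).__name__}: {exc}"
    if not estimates:
        raise EstimationError(
            "all estimator modes failed: "
            + "; ".join(f"{m}: {msg}" for m, msg in failures.items())
        )
    return estimates, failures
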