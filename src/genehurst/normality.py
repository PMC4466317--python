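"""Distribution testing of Hurst-exponent samples.

The scientific question downstream of per-gene Hurst estimation is
distributional: do the H values of a gene group (full gene set, essential,
nonessential) follow a normal / uniform / Poisson / exponential law?  The
workhorse is the one-sample Kolmogorov-Smirnov test with parameters
estimated from the sample and the *asymptotic* significance level — the
classical SPSS one-sample K-S dialect, deliberately without the Lilliefors
correction, because that is the procedure the group comparisons are defined
against.  A Monte-Carlo Lilliefors-corrected p-value is available as a
clearly labelled option for honest reanalysis: with estimated parameters
the plug-in asymptotic p is conservative (biased toward acceptance).

Poisson is a discrete family, so continuous H values are first integerized
(multiplied by ``poisson_scale`` and rounded); results for that family are
flagged ``integerized``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .exceptions import (
    DegenerateSampleError,
    DomainError,
    InputError,
)

FAMILIES = ("normal", "uniform", "poisson", "exponential")
GROUPS = ("full_gene_set", "essential", "nonessential")

#: hypothesis-acceptance threshold on the K-S significance level
ALPHA = 0.05


@dataclass(frozen=True)
class KSResult:
    """One-sample K-S outcome for one candidate family."""

    family: str
    n: int
    estimated_params: Mapping[str, float]
    D: float
    p: float
    integerized: bool = False

    @property
    def accepted(self) -> bool:
        """Distribution hypothesis accepted at the 0.05 level."""
        return self.p >= ALPHA


@dataclass(frozen=True)
class NormalityReport:
    """Per-group report: one KSResult per tested family."""

    group: str
    method: str
    results: tuple[KSResult, ...]
    sample_mean: float
    sample_sd: float
    n: int

    def result_for(self, family: str) -> KSResult:
        for r in self.results:
            if r.family == family:
                return r
        raise KeyError(family)


@dataclass(frozen=True)
class QQData:
    """Normal quantile-quantile data with Blom plotting positions."""

    ordered_sample: np.ndarray
    plotting_positions: np.ndarray
    theoretical_quantiles: np.ndarray


def ks_statistic(sample: Iterable[float], cdf: Callable[[np.ndarray], np.ndarray]) -> float:
    """Kolmogorov-Smirnov statistic D = sup |empirical CDF - F|.

    Ties collapse into a single empirical-CDF jump: D is evaluated on the
    distinct order statistics with cumulative tie counts.
    """
    x = np.sort(np.asarray(list(sample), dtype=float))
    n = x.size
    if n < 1:
        raise InputError("empty sample")
    values, counts = np.unique(x, return_counts=True)
    cum = np.cumsum(counts)
    upper = cum / n            # ECDF just after each distinct value
    lower = (cum - counts) / n  # ECDF just before
    f = np.asarray(cdf(values), dtype=float)
    d = float(np.max(np.maximum(upper - f, f - lower)))
    return min(max(d, 0.0), 1.0)


def ks_pvalue(D: float, n: int) -> float:
    """Asymptotic Kolmogorov significance level with Stephens' small-sample
    adjustment: lambda = (sqrt(n) + 0.12 + 0.11/sqrt(n)) * D, then

        p = 2 * sum_{k>=1} (-1)^(k-1) exp(-2 k^2 lambda^2),

    the series truncated once a term drops below 1e-12; clipped to [0, 1].
    """
    if not 0.0 <= D <= 1.0:
        raise DomainError(f"D must be in [0, 1], got {D}")
    if n < 1:
        raise DomainError("n must be >= 1")
    if D == 0.0:
        return 1.0
    lam = (np.sqrt(n) + 0.12 + 0.11 / np.sqrt(n)) * D
    total = 0.0
    for k in range(1, 100001):
        term = np.exp(-2.0 * k * k * lam * lam)
        total += (term if k % 2 == 1 else -term)
        if term < 1e-12:
            break
    return float(min(max(2.0 * total, 0.0), 1.0))


def _family_cdf_and_params(
    x: np.ndarray, family: str, poisson_scale: float
) -> tuple[Callable, dict[str, float], np.ndarray, bool]:
    """Plug-in parameter estimates and CDF for one family.

    Returns (cdf, params, sample_used, integerized).
    """
    if family == "normal":
        mean, sd = float(np.mean(x)), float(np.std(x, ddof=1))
        if sd == 0:
            raise DegenerateSampleError("sample sd is 0; normal fit degenerate")
        return sps.norm(mean, sd).cdf, {"mean": mean, "sd": sd}, x, False
    if family == "uniform":
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi == lo:
            raise DegenerateSampleError("min == max; uniform fit degenerate")
        return sps.uniform(lo, hi - lo).cdf, {"min": lo, "max": hi}, x, False
    if family == "exponential":
        if np.any(x < 0):
            raise DomainError("negative values; exponential requires x >= 0")
        mean = float(np.mean(x))
        if mean == 0:
            raise DegenerateSampleError("sample mean 0; exponential degenerate")
        return sps.expon(scale=mean).cdf, {"rate": 1.0 / mean}, x, False
    if family == "poisson":
        xi = np.round(x * poisson_scale)
        if np.any(xi < 0):
            raise DomainError("negative values; Poisson requires counts >= 0")
        lam = float(np.mean(xi))
        if lam == 0:
            raise DegenerateSampleError("integerized mean 0; Poisson degenerate")
        return sps.poisson(lam).cdf, {"rate": lam, "scale": poisson_scale}, xi, True
    raise DomainError(f"unknown family {family!r}; choose from {FAMILIES}")


def ks_test_family(
    sample: Iterable[float],
    family: str,
    poisson_scale: float = 100.0,
    lilliefors_mc: int = 0,
    seed: int = 0,
) -> KSResult:
    """One-sample K-S test of ``sample`` against an estimated family member.

    Parameters are plugged in from the sample (normal: mean/sd; uniform:
    min/max; exponential: rate = 1/mean; poisson: rate = mean of the
    integerized values) and the asymptotic significance is reported — the
    SPSS one-sample K-S convention.  Set ``lilliefors_mc`` to a positive
    replicate count for a Monte-Carlo Lilliefors-corrected p instead.
    """
    x = np.asarray(list(sample), dtype=float)
    if x.size < 8:
        raise InputError(f"need sample size >= 8, got {x.size}")
    cdf, params, used, integerized = _family_cdf_and_params(x, family, poisson_scale)
    d = ks_statistic(used, cdf)
    if lilliefors_mc > 0:
        p = _lilliefors_pvalue(used, family, d, poisson_scale, lilliefors_mc, seed)
    else:
        p = ks_pvalue(d, used.size)
    return KSResult(
        family=family, n=int(x.size), estimated_params=params,
        D=d, p=p, integerized=integerized,
    )


def _lilliefors_pvalue(
    x: np.ndarray, family: str, d_obs: float,
    poisson_scale: float, n_mc: int, seed: int,
) -> float:
    """Monte-Carlo null distribution of D with re-estimated parameters."""
    rng = np.random.default_rng(seed)
    n = x.size
    exceed = 0
    for _ in range(n_mc):
        if family == "normal":
            sim = rng.normal(np.mean(x), np.std(x, ddof=1), size=n)
        elif family == "uniform":
            sim = rng.uniform(np.min(x), np.max(x), size=n)
        elif family == "exponential":
            sim = rng.exponential(np.mean(x), size=n)
        else:  # poisson (x already integerized)
            sim = rng.poisson(np.mean(x), size=n).astype(float)
        cdf, _, used, _ = _family_cdf_and_params(sim, family, 1.0)
        if ks_statistic(used, cdf) >= d_obs:
            exceed += 1
    return (exceed + 1) / (n_mc + 1)


def qq_normal(sample: Iterable[float]) -> QQData:
    """Normal Q-Q data with Blom plotting positions (i - 3/8)/(n + 1/4).

    Theoretical quantiles use the sample mean and sd, matching the SPSS
    Q-Q convention; a straight line indicates normality.
    """
    x = np.sort(np.asarray(list(sample), dtype=float))
    n = x.size
    if n < 2:
        raise InputError("need sample size >= 2 for a Q-Q plot")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise DegenerateSampleError("sample sd is 0; Q-Q undefined")
    positions = (np.arange(1, n + 1) - 0.375) / (n + 0.25)
    theo = float(np.mean(x)) + sd * sps.norm.ppf(positions)
    return QQData(
        ordered_sample=x, plotting_positions=positions, theoretical_quantiles=theo
    )


@dataclass(frozen=True)
class GroupComparison:
    """Flags summarizing the essential-vs-full normality contrast."""

    essential_more_normal_than_full: bool | None
    p_essential_normal: float | None
    p_full_normal: float | None


def group_normality(
    h_by_group: Mapping[str, Sequence[float]],
    families: Sequence[str] = FAMILIES,
    method: str = "spec_smoothed",
    poisson_scale: float = 100.0,
    compare: bool = True,
) -> tuple[list[NormalityReport], GroupComparison]:
    """Per-group K-S reports plus the essential-vs-full comparison flag.

    ``h_by_group`` maps group names (``full_gene_set``, ``essential``,
    ``nonessential``) to per-gene Hurst values.  When ``compare`` is true,
    ``full_gene_set`` must be present so the comparison is well defined.
    """
    if not families:
        raise InputError("families must be non-empty")
    for fam in families:
        if fam not in FAMILIES:
            raise DomainError(f"unknown family {fam!r}")
    for group, values in h_by_group.items():
        if group not in GROUPS:
            raise DomainError(f"unknown group {group!r}; choose from {GROUPS}")
        if len(values) == 0:
            raise InputError(f"group {group!r} is empty")
    if compare and "full_gene_set" not in h_by_group:
        raise InputError("comparison requested but 'full_gene_set' group missing")

    reports: list[NormalityReport] = []
    for group, values in h_by_group.items():
        x = np.asarray(list(values), dtype=float)
        results = tuple(
            ks_test_family(x, fam, poisson_scale=poisson_scale) for fam in families
        )
        reports.append(
            NormalityReport(
                group=group, method=method, results=results,
                sample_mean=float(np.mean(x)), sample_sd=float(np.std(x, ddof=1)),
                n=int(x.size),
            )
        )

    comparison = GroupComparison(None, None, None)
    if compare and "normal" in families and "essential" in h_by_group:
        by_group = {r.group: r for r in reports}
        p_ess = by_group["essential"].result_for("normal").p
        p_full = by_group["full_gene_set"].result_for("normal").p
        comparison = GroupComparison(
            essential_more_normal_than_full=bool(p_ess > p_full),
            p_essential_normal=p_ess,
            p_full_normal=p_full,
        )
    return reports, comparison
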