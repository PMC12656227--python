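"""Method-comparison battery: Bland-Altman, RPC, proportional bias, ICC(A,1).

Agreement between the video-derived and IMU-derived scores is assessed on
paired subject x hand values.  A Lilliefors test on the differences gates
the Bland-Altman variant: parametric (mean +- 1.96 SD, with the classic
Bland-Altman variance formulas for the CIs) when normality is tenable,
non-parametric (median and empirical 2.5th/97.5th percentiles, with
percentile-bootstrap CIs over 5000 unit resamples) otherwise.  Both variants
are always computed and reported so neither is hidden by the gate.

The reproducibility coefficient (RPC) is 1.96*SD in the parametric variant
and 1.45*IQR in the non-parametric one (1.45*IQR estimates 1.96*SD for a
normal distribution).  Absolute agreement is summarized by ICC(A,1): the
two-way, absolute-agreement, single-measures intraclass correlation of
McGraw & Wong, with a percentile-bootstrap CI over unit resamples.
Proportional bias is the OLS slope of differences on per-unit means.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DegenerateDataError",
    "InsufficientDataError",
    "DegenerateRegressorError",
    "UndefinedICCError",
    "UnstableBootstrapError",
    "PairedDifferences",
    "LimitsOfAgreement",
    "AgreementResult",
    "lilliefors_statistic",
    "lilliefors",
    "loa_parametric",
    "loa_nonparametric",
    "proportional_bias",
    "icc_a1",
    "icc_bootstrap_ci",
    "agreement_report",
]

DEFAULT_N_BOOT = 5000
LOA_Z = 1.96  # classic Bland-Altman multiplier
RPC_NONPARAMETRIC_IQR_FACTOR = 1.45


class DegenerateDataError(ValueError):
    """Zero-variance data where spread is required."""


class InsufficientDataError(ValueError):
    """Too few observations for the requested statistic."""


class DegenerateRegressorError(ValueError):
    """The regressor is constant; no slope is identified."""


class UndefinedICCError(ValueError):
    """All matrix entries identical; the ICC ratio is 0/0."""


class UnstableBootstrapError(RuntimeError):
    """Most bootstrap resamples leave the statistic undefined."""


@dataclass(frozen=True)
class PairedDifferences:
    """Unit-level method differences for one variable.

    ``d`` holds method1 - method2 per unit (orientation fixed upstream as
    IMU - video), ``m`` the per-unit mean of the two methods.  The two
    per-method value vectors are recoverable as ``m + d/2`` and ``m - d/2``.
    """

    unit_ids: tuple
    d: np.ndarray
    m: np.ndarray
    variable_label: str

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        m = np.asarray(self.m, dtype=float)
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "m", m)
        if d.size != m.size or d.size < 3:
            raise InsufficientDataError("need matched d and m with n >= 3")

    @property
    def n_units(self) -> int:
        return int(self.d.size)

    def method_matrix(self) -> np.ndarray:
        """n x 2 matrix of the underlying per-method values (method1, method2)."""
        return np.column_stack([self.m + self.d / 2.0, self.m - self.d / 2.0])


@dataclass(frozen=True)
class LimitsOfAgreement:
    variant: Literal["parametric", "nonparametric"]
    bias: float
    loa_low: float
    loa_high: float
    ci_bias: tuple[float, float]
    ci_loa_low: tuple[float, float]
    ci_loa_high: tuple[float, float]
    rpc: float

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "bias": self.bias,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "ci_bias": list(self.ci_bias),
            "ci_loa_low": list(self.ci_loa_low),
            "ci_loa_high": list(self.ci_loa_high),
            "rpc": self.rpc,
        }


@dataclass(frozen=True)
class AgreementResult:
    """Machine-readable agreement summary for one variable."""

    variable_label: str
    n_units: int
    normality_stat: float
    normality_p: float
    method_selected: Literal["parametric", "nonparametric"]
    parametric: LimitsOfAgreement
    nonparametric: LimitsOfAgreement
    slope: float
    slope_p: float
    icc: float
    icc_ci: tuple[float, float]

    @property
    def selected(self) -> LimitsOfAgreement:
        return (
            self.nonparametric
            if self.method_selected == "nonparametric"
            else self.parametric
        )

    def to_dict(self) -> dict:
        sel = self.selected
        return {
            "variable": self.variable_label,
            "n_units": self.n_units,
            "normality_stat": self.normality_stat,
            "normality_p": self.normality_p,
            "method_selected": self.method_selected,
            "bias": sel.bias,
            "loa_low": sel.loa_low,
            "loa_high": sel.loa_high,
            "rpc": sel.rpc,
            "parametric": self.parametric.to_dict(),
            "nonparametric": self.nonparametric.to_dict(),
            "slope": self.slope,
            "slope_p": self.slope_p,
            "icc": self.icc,
            "icc_ci": list(self.icc_ci),
        }


# ---------------------------------------------------------------------------
# Normality gate
# ---------------------------------------------------------------------------

def lilliefors_statistic(d: np.ndarray) -> float:
    """Kolmogorov-Smirnov distance to a normal with estimated mean and SD."""
    d = np.sort(np.asarray(d, dtype=float))
    n = d.size
    if n < 3:
        raise InsufficientDataError("need n >= 3 for the statistic")
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("zero-variance differences")
    cdf = stats.norm.cdf((d - d.mean()) / sd)
    ranks = np.arange(1, n + 1)
    d_plus = np.max(ranks / n - cdf)
    d_minus = np.max(cdf - (ranks - 1) / n)
    return float(max(d_plus, d_minus))


def lilliefors(d: np.ndarray) -> tuple[float, float]:
    """Lilliefors normality test: (statistic, p).

    The p-value interpolates the small-sample Lilliefors table (statsmodels'
    implementation, which extends to large n via an asymptotic formula).
    """
    d = np.asarray(d, dtype=float)
    if d.size < 4:
        raise InsufficientDataError("need n >= 4 for a p-value")
    if d.std(ddof=1) == 0:
        raise DegenerateDataError("zero-variance differences")
    from statsmodels.stats.diagnostic import lilliefors as _sm_lilliefors

    stat, p = _sm_lilliefors(d, dist="norm", pvalmethod="table")
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# Limits of agreement
# ---------------------------------------------------------------------------

def loa_parametric(d: np.ndarray, alpha: float = 0.05) -> LimitsOfAgreement:
    """Classic Bland-Altman limits: mean +- 1.96 SD with analytic CIs.

    Var(bias) = s^2/n; Var(LoA) = s^2 (1/n + 1.96^2 / (2(n-1))); CIs use the
    t(n-1) quantile.
    """
    d = np.asarray(d, dtype=float)
    n = d.size
    if n < 3:
        raise InsufficientDataError("need n >= 3")
    bias = float(d.mean())
    s = float(d.std(ddof=1))
    loa_low = bias - LOA_Z * s
    loa_high = bias + LOA_Z * s
    t_q = stats.t.ppf(1 - alpha / 2.0, n - 1)
    se_bias = s / np.sqrt(n)
    se_loa = s * np.sqrt(1.0 / n + LOA_Z**2 / (2.0 * (n - 1)))
    return LimitsOfAgreement(
        variant="parametric",
        bias=bias,
        loa_low=loa_low,
        loa_high=loa_high,
        ci_bias=(bias - t_q * se_bias, bias + t_q * se_bias),
        ci_loa_low=(loa_low - t_q * se_loa, loa_low + t_q * se_loa),
        ci_loa_high=(loa_high - t_q * se_loa, loa_high + t_q * se_loa),
        rpc=LOA_Z * s,
    )


def loa_nonparametric(
    d: np.ndarray,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> LimitsOfAgreement:
    """Distribution-free limits: median and empirical 2.5/97.5 percentiles.

    Quantiles use linear interpolation between order statistics ("type 7").
    CIs are percentile intervals of the same statistics over ``n_boot``
    resamples of units with replacement; RPC is 1.45 * IQR.
    """
    d = np.asarray(d, dtype=float)
    n = d.size
    if n < 3:
        raise InsufficientDataError("need n >= 3")
    if n < 8:
        warnings.warn(
            "non-parametric limits are unreliable below n = 8", stacklevel=2
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    bias = float(np.median(d))
    loa_low, loa_high = np.percentile(d, [2.5, 97.5])
    q25, q75 = np.percentile(d, [25.0, 75.0])

    idx = rng.integers(0, n, size=(n_boot, n))
    resamples = d[idx]
    boot_bias = np.median(resamples, axis=1)
    boot_low = np.percentile(resamples, 2.5, axis=1)
    boot_high = np.percentile(resamples, 97.5, axis=1)

    def _ci(v: np.ndarray) -> tuple[float, float]:
        lo, hi = np.percentile(v, [2.5, 97.5])
        return float(lo), float(hi)

    return LimitsOfAgreement(
        variant="nonparametric",
        bias=bias,
        loa_low=float(loa_low),
        loa_high=float(loa_high),
        ci_bias=_ci(boot_bias),
        ci_loa_low=_ci(boot_low),
        ci_loa_high=_ci(boot_high),
        rpc=RPC_NONPARAMETRIC_IQR_FACTOR * float(q75 - q25),
    )


def proportional_bias(d: np.ndarray, m: np.ndarray) -> tuple[float, float]:
    """OLS slope of differences on per-unit means, with its two-sided p."""
    d = np.asarray(d, dtype=float)
    m = np.asarray(m, dtype=float)
    if d.size != m.size or d.size < 3:
        raise InsufficientDataError("need matched d and m with n >= 3")
    if np.ptp(m) == 0:
        raise DegenerateRegressorError("per-unit means are constant")
    if np.ptp(d) == 0:
        return 0.0, float("nan")
    res = stats.linregress(m, d)
    return float(res.slope), float(res.pvalue)


# ---------------------------------------------------------------------------
# ICC(A,1)
# ---------------------------------------------------------------------------

def _icc_a1_batch(x: np.ndarray) -> np.ndarray:
    """Vectorized ICC(A,1) over a (B, n, k) stack; NaN where undefined."""
    B, n, k = x.shape
    grand = x.mean(axis=(1, 2), keepdims=True)
    row_means = x.mean(axis=2)
    col_means = x.mean(axis=1)
    ssr = k * ((row_means - grand[:, :, 0]) ** 2).sum(axis=1)
    ssc = n * ((col_means - grand[:, 0, :]) ** 2).sum(axis=1)
    sst = ((x - grand) ** 2).sum(axis=(1, 2))
    sse = np.maximum(sst - ssr - ssc, 0.0)
    # snap float residue to an exact zero so e.g. identical columns give ICC 1
    sse[sse <= 1e-12 * np.maximum(sst, 1e-300)] = 0.0
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    scale = np.maximum(sst, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = (msr - mse) / denom
    undefined = (sst <= 1e-12 * scale) | (np.abs(denom) <= 1e-15 * scale)
    icc[undefined] = np.nan
    return icc


def icc_a1(x: np.ndarray) -> float:
    """ICC(A,1): two-way ANOVA, absolute agreement, single measures.

    ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E)) with row
    (unit), column (method) and error mean squares from the complete n x k
    two-way layout.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("x must be a 2-D units x measurements matrix")
    n, k = x.shape
    if n < 3 or k < 2:
        raise InsufficientDataError("need n >= 3 units and k >= 2 measurements")
    if not np.all(np.isfinite(x)):
        raise ValueError("matrix must be complete and finite")
    icc = _icc_a1_batch(x[None, :, :])[0]
    if np.isnan(icc):
        raise UndefinedICCError("all values identical; ICC undefined")
    return float(icc)


def icc_bootstrap_ci(
    x: np.ndarray,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    alpha: float = 0.05,
    max_redraw_rounds: int = 100,
) -> tuple[float, float]:
    """Percentile bootstrap CI for ICC(A,1), resampling units (rows).

    Resamples with an undefined ICC (all entries identical) are redrawn up to
    ``max_redraw_rounds`` times; if more than half of the first round is
    undefined the data cannot support a bootstrap and an error is raised.
    """
    x = np.asarray(x, dtype=float)
    icc_a1(x)  # validates shape and definedness
    n = x.shape[0]
    if rng is None:
        rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    iccs = _icc_a1_batch(x[idx])
    bad = np.isnan(iccs)
    if bad.mean() > 0.5:
        raise UnstableBootstrapError(
            f"{bad.mean():.0%} of resamples leave ICC undefined"
        )
    rounds = 0
    while bad.any():
        rounds += 1
        if rounds > max_redraw_rounds:
            raise UnstableBootstrapError("undefined resamples persist after redraws")
        redraw = rng.integers(0, n, size=(int(bad.sum()), n))
        iccs[bad] = _icc_a1_batch(x[redraw])
        bad = np.isnan(iccs)
    lo, hi = np.percentile(iccs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------

def agreement_report(
    paired: PairedDifferences,
    alpha: float = 0.05,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> AgreementResult:
    """Run the full agreement battery on one paired variable.

    The Lilliefors gate selects the non-parametric variant iff p < alpha;
    both variants are computed and reported regardless.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    d, m = paired.d, paired.m
    if np.ptp(d) == 0.0:
        # perfect (constant-difference) agreement: the normality gate is
        # undefined; both LoA variants collapse onto the constant
        stat, p = float("nan"), float("nan")
    else:
        stat, p = lilliefors(d)
    par = loa_parametric(d, alpha=alpha)
    nonpar = loa_nonparametric(d, n_boot=n_boot, rng=rng)
    slope, slope_p = proportional_bias(d, m)
    x = paired.method_matrix()
    icc = icc_a1(x)
    icc_ci = icc_bootstrap_ci(x, n_boot=n_boot, rng=rng, alpha=alpha)
    return AgreementResult(
        variable_label=paired.variable_label,
        n_units=paired.n_units,
        normality_stat=stat,
        normality_p=p,
        method_selected="nonparametric" if p < alpha else "parametric",  # NaN p -> parametric
        parametric=par,
        nonparametric=nonpar,
        slope=slope,
        slope_p=slope_p,
        icc=icc,
        icc_ci=icc_ci,
    )
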