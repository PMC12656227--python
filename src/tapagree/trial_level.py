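"""Trial-level mixed-effects bias analysis and ICC power / sample size.

At the trial level the repeated measurements are nested in subjects, so the
between-method difference is modelled with a random-intercept mixed model

    d_ij = beta0 + beta1 * (m_ij - mean(m)) + u_i + eps_ij,

fitted by REML: ``u_i`` is a subject random intercept (SD ``sigma_subject``)
and ``eps_ij`` residual intra-subject noise (SD ``sigma_resid``).  The slope
regressor is centred at the grand mean so the intercept reads as the bias at
an average-magnitude trial; the marginal mean of d is reported separately as
``mean_bias``.

Sample-size planning for the ICC uses the Walter-Eliasziw-Donner
approximation for testing H0: rho = rho0 against rho = rho1 > rho0 with k
measurements per subject.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ModelFitError",
    "InvalidSpecError",
    "MixedModelResult",
    "PowerSpec",
    "fit_mixed_bias",
    "icc_sample_size",
    "icc_power",
]

logger = logging.getLogger(__name__)


class ModelFitError(RuntimeError):
    """The mixed model cannot be fitted on the supplied design."""


class InvalidSpecError(ValueError):
    """Power specification violates its constraints."""


@dataclass(frozen=True)
class MixedModelResult:
    mean_bias: float
    intercept: float
    slope: float
    slope_se: float
    slope_p: float
    sigma_subject: float
    sigma_resid: float
    n_trials_used: int
    n_subjects: int
    degenerate: bool = False
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "mean_bias": self.mean_bias,
            "intercept": self.intercept,
            "slope": self.slope,
            "slope_se": self.slope_se,
            "slope_p": self.slope_p,
            "sigma_subject": self.sigma_subject,
            "sigma_resid": self.sigma_resid,
            "n_trials_used": self.n_trials_used,
            "n_subjects": self.n_subjects,
            "degenerate": self.degenerate,
            "note": self.note,
        }


@dataclass(frozen=True)
class PowerSpec:
    """ICC hypothesis-test sizing: rho1 > rho0, k measurements per subject."""

    rho0: float
    rho1: float
    alpha: float = 0.05
    power_target: float = 0.80
    k: int = 2
    sidedness: Literal["one", "two"] = "one"

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho0 < 1.0 or not 0.0 <= self.rho1 < 1.0:
            raise InvalidSpecError("rho0 and rho1 must lie in [0, 1)")
        if not 0.0 < self.alpha < 1.0 or not 0.0 < self.power_target < 1.0:
            raise InvalidSpecError("alpha and power_target must lie in (0, 1)")
        if self.k < 2:
            raise InvalidSpecError("k must be >= 2")
        if self.sidedness not in ("one", "two"):
            raise InvalidSpecError("sidedness must be 'one' or 'two'")

    @property
    def alpha_eff(self) -> float:
        return self.alpha if self.sidedness == "one" else self.alpha / 2.0


# ---------------------------------------------------------------------------
# Mixed-effects bias model
# ---------------------------------------------------------------------------

def fit_mixed_bias(
    d: np.ndarray,
    m: np.ndarray,
    subject_ids: Sequence,
    hand_ids: Sequence | None = None,
    *,
    group_by_hand: bool = False,
) -> MixedModelResult:
    """Fit the random-intercept bias model at the trial level.

    ``group_by_hand=True`` nests the random intercept in subject x hand
    instead of subject.  If the random-intercept variance collapses to zero
    (or the REML fit fails) the model degrades gracefully to OLS with a
    logged note; if the differences have no variance at all the fit is
    reported as degenerate with both SDs at zero.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    d = np.asarray(d, dtype=float)
    m = np.asarray(m, dtype=float)
    subjects = np.asarray(subject_ids)
    if not (d.size == m.size == subjects.size):
        raise ModelFitError("d, m and subject_ids must have equal length")
    if hand_ids is not None and len(hand_ids) != d.size:
        raise ModelFitError("hand_ids length mismatch")
    uniq, counts = np.unique(subjects, return_counts=True)
    if uniq.size < 5:
        raise ModelFitError("need >= 5 subjects")
    if counts.max() < 2:
        raise ModelFitError("need >= 2 trials for at least one subject")

    mean_bias = float(d.mean())
    mc = m - m.mean()
    n = d.size
    if np.ptp(d) == 0.0:
        return MixedModelResult(
            mean_bias=mean_bias,
            intercept=mean_bias,
            slope=0.0,
            slope_se=float("nan"),
            slope_p=float("nan"),
            sigma_subject=0.0,
            sigma_resid=0.0,
            n_trials_used=n,
            n_subjects=int(uniq.size),
            degenerate=True,
            note="differences are constant; variances degenerate to 0",
        )
    if np.ptp(mc) == 0.0:
        raise ModelFitError("trial means are constant; slope not identified")

    if group_by_hand:
        if hand_ids is None:
            raise ModelFitError("group_by_hand=True requires hand_ids")
        groups = np.array(
            [f"{s}|{h}" for s, h in zip(subjects, hand_ids)], dtype=object
        )
    else:
        groups = subjects
    exog = sm.add_constant(mc)

    def _ols_result(note: str) -> MixedModelResult:
        ols = sm.OLS(d, exog).fit()
        logger.info("mixed model degraded to OLS: %s", note)
        return MixedModelResult(
            mean_bias=mean_bias,
            intercept=float(ols.params[0]),
            slope=float(ols.params[1]),
            slope_se=float(ols.bse[1]),
            slope_p=float(ols.pvalues[1]),
            sigma_subject=0.0,
            sigma_resid=float(np.sqrt(ols.scale)),
            n_trials_used=n,
            n_subjects=int(uniq.size),
            note=note,
        )

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            model = sm.MixedLM(d, exog, groups=groups)
            fit = model.fit(reml=True)
    except (np.linalg.LinAlgError, ValueError) as err:
        return _ols_result(f"REML fit failed ({err}); refit by OLS")

    var_u = float(np.asarray(fit.cov_re)[0, 0])
    if not np.isfinite(var_u) or var_u <= 1e-12 * max(float(np.var(d)), 1e-300):
        return _ols_result("random-intercept variance estimated at 0")
    return MixedModelResult(
        mean_bias=mean_bias,
        intercept=float(fit.params[0]),
        slope=float(fit.params[1]),
        slope_se=float(fit.bse[1]),
        slope_p=float(fit.pvalues[1]),
        sigma_subject=float(np.sqrt(var_u)),
        sigma_resid=float(np.sqrt(fit.scale)),
        n_trials_used=n,
        n_subjects=int(uniq.size),
    )


# ---------------------------------------------------------------------------
# ICC power / sample size (Walter, Eliasziw & Donner)
# ---------------------------------------------------------------------------

def _ln_c0(rho0: float, rho1: float, k: int) -> float:
    c0 = (1.0 + k * rho0 / (1.0 - rho0)) / (1.0 + k * rho1 / (1.0 - rho1))
    return math.log(c0)


def icc_sample_size(spec: PowerSpec) -> int:
    """Minimum subjects to detect rho1 against rho0 at the spec's alpha/power.

    n = ceil(1 + 2 (z_{1-alpha'} + z_{power})^2 k / ((k-1) ln^2 C0)) with
    C0 = (1 + k rho0/(1-rho0)) / (1 + k rho1/(1-rho1)).
    """
    if spec.rho1 <= spec.rho0:
        raise InvalidSpecError("rho1 must exceed rho0")
    z_a = stats.norm.ppf(1.0 - spec.alpha_eff)
    z_b = stats.norm.ppf(spec.power_target)
    ln_c0 = _ln_c0(spec.rho0, spec.rho1, spec.k)
    n = 1.0 + 2.0 * (z_a + z_b) ** 2 * spec.k / ((spec.k - 1) * ln_c0**2)
    return int(math.ceil(n - 1e-12))


def icc_power(n: int, spec: PowerSpec) -> float:
    """Achieved power of the same approximation at ``n`` subjects."""
    if n < 2:
        raise InvalidSpecError("n must be >= 2")
    if spec.rho1 < spec.rho0:
        raise InvalidSpecError("rho1 must be >= rho0")
    if spec.rho1 == spec.rho0:
        return spec.alpha_eff
    z_a = stats.norm.ppf(1.0 - spec.alpha_eff)
    ln_c0 = _ln_c0(spec.rho0, spec.rho1, spec.k)
    z_b = math.sqrt((n - 1.0) * (spec.k - 1) * ln_c0**2 / (2.0 * spec.k)) - z_a
    return float(stats.norm.cdf(z_b))
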