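"""Power-law modelling of age over serum AMH.

The model is age = β0·AMH^(−β1), fitted by ordinary least squares after the
log–log linearization ln(age) = ln β0 − β1·ln(AMH). Age at menopause is the
model evaluated at an AMH cutoff (default 0.2 ng/mL); the decline curve is the
algebraic inverse AMH(age) = (age/β0)^(−1/β1) with its analytic derivative.

The regression direction is age-on-AMH, exactly as the model is written, even
though AMH is biologically the response: this is the formulation whose printed
coefficients reproduce the printed menopause predictions. AMH values ≤ 0 are a
hard error — callers must apply an explicit detection-limit policy (e.g.
:func:`apply_loq_policy`) rather than relying on a silent offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import DegenerateDesignError, DomainError, NonInvertibleModelError, UsageError

DEFAULT_CUTOFF_NG_ML = 0.2


@dataclass(frozen=True)
class PowerFit:
    """Fitted (or externally supplied) coefficients of age = β0·AMH^(−β1).

    ``n``, ``r_squared`` and ``residual_sd`` (both on the log–log scale) are
    None when the coefficients were supplied rather than fitted.
    ``log_beta0`` is derived, so it always equals ln(beta0) exactly.
    """

    beta0: float
    beta1: float
    group: str
    n: int | None = None
    r_squared: float | None = None
    residual_sd: float | None = None

    def __post_init__(self):
        if not (self.beta0 > 0 and math.isfinite(self.beta0)):
            raise UsageError(f"beta0 must be finite and > 0, got {self.beta0}")
        if not math.isfinite(self.beta1):
            raise UsageError(f"beta1 must be finite, got {self.beta1}")
        if self.n is not None and self.n < 3:
            raise UsageError(f"a fitted model needs n >= 3 points, got n={self.n}")
        if self.r_squared is not None and not (0.0 <= self.r_squared <= 1.0):
            raise UsageError(f"r_squared must lie in [0, 1], got {self.r_squared}")

    @property
    def log_beta0(self) -> float:
        return math.log(self.beta0)

    @classmethod
    def from_coefficients(cls, beta0: float, beta1: float, group: str) -> "PowerFit":
        """Build a fit from published coefficients (no data required)."""
        return cls(beta0=beta0, beta1=beta1, group=group)


@dataclass(frozen=True)
class MenopausePrediction:
    """Predicted age at which the modelled AMH curve crosses the cutoff."""

    cutoff: float
    predicted_age: float
    group: str
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self):
        if self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low <= self.predicted_age <= self.ci_high):
                raise UsageError(
                    "confidence interval must bracket the point prediction: "
                    f"[{self.ci_low}, {self.ci_high}] vs {self.predicted_age}"
                )


@dataclass(frozen=True)
class DeclineCurve:
    """AMH(age) and its analytic rate d(AMH)/d(age) on a uniform age grid."""

    ages: np.ndarray
    amh_values: np.ndarray
    rates: np.ndarray
    group: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "amh": self.amh_values, "rate": self.rates})


def _loglog_design(ages, amh) -> tuple[np.ndarray, np.ndarray]:
    ages = np.asarray(ages, dtype=float)
    amh = np.asarray(amh, dtype=float)
    if ages.shape != amh.shape or ages.ndim != 1:
        raise UsageError("ages and amh must be equal-length 1-D sequences")
    if ages.size < 3:
        raise UsageError(f"need at least 3 points, got {ages.size}")
    if not np.all(np.isfinite(ages)) or not np.all(np.isfinite(amh)):
        raise DomainError("ages and amh must all be finite")
    if np.any(amh <= 0):
        raise DomainError(
            "AMH values <= 0 cannot enter the log-scale fit; exclude them or apply an "
            "explicit limit-of-quantification policy (see apply_loq_policy)"
        )
    if np.any(ages <= 0):
        raise DomainError("ages must all be > 0")
    if np.unique(amh).size < 3:
        raise DegenerateDesignError(
            f"need at least 3 distinct AMH values, got {np.unique(amh).size}"
        )
    return np.log(amh), np.log(ages)


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form simple OLS: returns (slope, intercept)."""
    xm, ym = x.mean(), y.mean()
    dx = x - xm
    slope = float(dx @ (y - ym) / (dx @ dx))
    return slope, float(ym - slope * xm)


def apply_loq_policy(amh, loq: float) -> np.ndarray:
    """Replace AMH values below a stated limit of quantification with loq/2.

    An explicit, opt-in alternative to erroring on non-positive AMH.
    """
    if loq <= 0:
        raise UsageError(f"limit of quantification must be > 0, got {loq}")
    amh = np.asarray(amh, dtype=float).copy()
    amh[amh < loq] = loq / 2.0
    return amh


def fit_power_model(ages, amh, group: str) -> PowerFit:
    """Least-squares fit of age = β0·AMH^(−β1) on the log–log scale.

    β0 = exp(intercept) and β1 = −slope of the OLS line of ln(age) on ln(AMH);
    r² and the residual SD are reported on the log–log scale. Requires at least
    3 points with 3 distinct AMH values and strictly positive ages and AMH.
    """
    x, y = _loglog_design(ages, amh)
    slope, intercept = _ols_line(x, y)
    resid = y - (intercept + slope * x)
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0.0 else max(0.0, min(1.0, 1.0 - sse / sst))
    n = x.size
    residual_sd = math.sqrt(sse / (n - 2)) if n > 2 else float("nan")
    return PowerFit(
        beta0=math.exp(intercept),
        beta1=-slope,
        group=group,
        n=int(n),
        r_squared=r2,
        residual_sd=residual_sd,
    )


def predict_age_from_amh(fit: PowerFit, amh):
    """Evaluate age = β0·AMH^(−β1); accepts a scalar or array of AMH > 0."""
    amh_arr = np.asarray(amh, dtype=float)
    if np.any(amh_arr <= 0):
        raise DomainError(f"AMH must be > 0, got {amh}")
    out = fit.beta0 * amh_arr ** (-fit.beta1)
    return float(out) if np.isscalar(amh) or amh_arr.ndim == 0 else out


def predict_amh_at_age(fit: PowerFit, age):
    """Invert the model: AMH(age) = (age/β0)^(−1/β1). Requires β1 ≠ 0."""
    if fit.beta1 == 0:
        raise NonInvertibleModelError("beta1 = 0: AMH does not determine age")
    age_arr = np.asarray(age, dtype=float)
    if np.any(age_arr <= 0):
        raise DomainError(f"age must be > 0, got {age}")
    out = (age_arr / fit.beta0) ** (-1.0 / fit.beta1)
    return float(out) if np.isscalar(age) or age_arr.ndim == 0 else out


def predict_menopause_age(fit: PowerFit, cutoff: float = DEFAULT_CUTOFF_NG_ML) -> MenopausePrediction:
    """Predicted menopause age: the model evaluated at the AMH cutoff."""
    if cutoff <= 0:
        raise DomainError(f"cutoff must be > 0 ng/mL, got {cutoff}")
    return MenopausePrediction(
        cutoff=cutoff,
        predicted_age=predict_age_from_amh(fit, cutoff),
        group=fit.group,
    )


def decline_curve(fit: PowerFit, age_start: float, age_end: float, n_points: int) -> DeclineCurve:
    """Evaluate AMH(age) and d(AMH)/d(age) = −AMH(age)/(β1·age) on a uniform grid."""
    if not (0 < age_start < age_end):
        raise UsageError(f"need 0 < age_start < age_end, got [{age_start}, {age_end}]")
    if n_points < 2:
        raise UsageError(f"n_points must be >= 2, got {n_points}")
    ages = np.linspace(age_start, age_end, n_points)
    amh = predict_amh_at_age(fit, ages)
    rates = -amh / (fit.beta1 * ages)
    return DeclineCurve(ages=ages, amh_values=amh, rates=rates, group=fit.group)


@dataclass(frozen=True)
class DeclineComparison:
    """Per-age comparison of two decline rates plus summary win fractions."""

    table: pd.DataFrame  # columns: age, rate_a, rate_b, faster ('a'|'b'|'tie')
    fraction_a: float
    fraction_b: float
    fraction_tie: float
    group_a: str
    group_b: str


def compare_decline(fit_a: PowerFit, fit_b: PowerFit, age_grid) -> DeclineComparison:
    """Report, age by age, which model's AMH declines faster in absolute value.

    No global verdict is asserted: the ordering of |d(AMH)/d(age)| between two
    power laws can change along the age axis, so the result carries the
    per-age verdicts and the fraction of grid ages won by each fit.
    """
    ages = np.asarray(age_grid, dtype=float)
    if ages.ndim != 1 or ages.size < 1 or np.any(ages <= 0):
        raise UsageError("age_grid must be a 1-D sequence of positive ages")
    rate_a = decline_curve_rates(fit_a, ages)
    rate_b = decline_curve_rates(fit_b, ages)
    abs_a, abs_b = np.abs(rate_a), np.abs(rate_b)
    tie = np.isclose(abs_a, abs_b, rtol=1e-12, atol=0.0)
    faster = np.where(tie, "tie", np.where(abs_a > abs_b, "a", "b"))
    table = pd.DataFrame({"age": ages, "rate_a": rate_a, "rate_b": rate_b, "faster": faster})
    n = ages.size
    return DeclineComparison(
        table=table,
        fraction_a=float(np.sum(faster == "a")) / n,
        fraction_b=float(np.sum(faster == "b")) / n,
        fraction_tie=float(np.sum(tie)) / n,
        group_a=fit_a.group,
        group_b=fit_b.group,
    )


def decline_curve_rates(fit: PowerFit, ages: np.ndarray) -> np.ndarray:
    """d(AMH)/d(age) at the given ages (ng/mL per year)."""
    amh = predict_amh_at_age(fit, ages)
    return -np.asarray(amh) / (fit.beta1 * np.asarray(ages, dtype=float))


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _count_distinct_rows(sorted_rows: np.ndarray) -> np.ndarray:
    return 1 + np.sum(np.diff(sorted_rows, axis=1) > 0, axis=1)


def bootstrap_menopause_ci(
    ages,
    amh,
    group: str,
    cutoff: float = DEFAULT_CUTOFF_NG_ML,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
) -> MenopausePrediction:
    """Case-resampling bootstrap percentile interval for the menopause age.

    Subjects are resampled with replacement; each replicate is refitted with the
    same closed-form OLS and the model is evaluated at the cutoff. Replicates
    whose resample has fewer than 3 distinct AMH values are redrawn, capped at
    10·n_boot total draws. Deterministic given the seed.
    """
    if n_boot < 100:
        raise UsageError(f"n_boot must be >= 100, got {n_boot}")
    if not (0.0 < level < 1.0):
        raise UsageError(f"level must lie in (0, 1), got {level}")
    x, y = _loglog_design(ages, amh)
    point_fit_slope, point_fit_intercept = _ols_line(x, y)
    point_age = math.exp(point_fit_intercept) * cutoff ** point_fit_slope
    if cutoff <= 0:
        raise DomainError(f"cutoff must be > 0, got {cutoff}")

    rng = np.random.default_rng(seed)
    n = x.size
    collected: list[np.ndarray] = []
    n_collected = 0
    attempts = 0
    max_attempts = 10 * n_boot
    while n_collected < n_boot:
        want = n_boot - n_collected
        if attempts + want > max_attempts:
            want = max_attempts - attempts
            if want <= 0:
                raise DegenerateDesignError(
                    f"exceeded {max_attempts} bootstrap draws without {n_boot} "
                    "non-degenerate replicates"
                )
        idx = rng.integers(0, n, size=(want, n))
        attempts += want
        xb = x[idx]
        ok = _count_distinct_rows(np.sort(xb, axis=1)) >= 3
        if np.any(ok):
            collected.append(idx[ok])
            n_collected += int(np.sum(ok))
    idx = np.vstack(collected)[:n_boot]

    xb, yb = x[idx], y[idx]
    xm = xb.mean(axis=1, keepdims=True)
    ym = yb.mean(axis=1, keepdims=True)
    dx = xb - xm
    slopes = np.sum(dx * (yb - ym), axis=1) / np.sum(dx * dx, axis=1)
    intercepts = ym[:, 0] - slopes * xm[:, 0]
    boot_ages = np.exp(intercepts) * cutoff ** slopes

    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(boot_ages, [alpha, 1.0 - alpha])
    # Percentile endpoints can sit on the far side of the full-sample point
    # estimate in tiny or heavily skewed samples; widen to bracket it.
    lo = min(float(lo), point_age)
    hi = max(float(hi), point_age)
    return MenopausePrediction(
        cutoff=cutoff, predicted_age=point_age, group=group, ci_low=lo, ci_high=hi
    )
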