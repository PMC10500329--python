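"""Heat-tolerance statistics from tube-level survival assays.

Workers are held for a fixed time at a series of constant temperatures and
scored moribund/alive per tube.  Death probability is modelled as
``logit(P(death)) = beta0 + beta1 * T`` so the median lethal temperature is
``LT50 = -beta0 / beta1``.  The module provides the maximum-likelihood fit
(with a Jeffreys-prior penalized fallback for separated data), a ratio test
for comparing LT50s between species, the upper thermal limit from a one-way
ANOVA with Tukey HSD contrasts, and the width of the survival decline.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


class ThermalFitError(ValueError):
    """Raised when a dose-response fit is not identifiable."""


@dataclass(frozen=True)
class SurvivalObservation:
    """One tube at one assay temperature."""

    species_id: str
    temperature: float
    tube_id: str
    n_total: int
    n_dead: int

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError(
                f"tube {self.tube_id}: n_total must be positive, got {self.n_total}"
            )
        if not 0 <= self.n_dead <= self.n_total:
            raise ValueError(
                f"tube {self.tube_id}: n_dead={self.n_dead} outside [0, {self.n_total}]"
            )

    @property
    def survival(self) -> float:
        return 1.0 - self.n_dead / self.n_total


@dataclass
class DoseResponseFit:
    """Binomial logit fit of death probability against temperature."""

    beta0: float
    beta1: float
    cov: np.ndarray
    lt50: float
    se_lt50: float
    ci95: tuple[float, float]
    converged: bool
    method: str  # "ml" or "firth"
    n_obs: int

    def predict(self, temperature) -> np.ndarray:
        """Death probability at the given temperature(s)."""
        eta = self.beta0 + self.beta1 * np.asarray(temperature, dtype=float)
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class RatioTestResult:
    ratio: float
    log_ratio_se: float
    ci95: tuple[float, float]
    z: float
    p: float


@dataclass
class UTLResult:
    utl: float
    anova_f: float
    anova_p: float
    tukey: dict[float, float]  # temperature -> adjusted p vs reference
    reference_temperature: float
    degenerate: bool = False
    note: str = ""


@dataclass
class DeclineWidth:
    t_high: float | None
    t_zero: float | None
    width: float | None
    upper: float
    lower: float
    reason: str = ""
    non_monotone: bool = False


def _design(observations: list[SurvivalObservation]):
    t = np.array([o.temperature for o in observations], dtype=float)
    n = np.array([o.n_total for o in observations], dtype=float)
    y = np.array([o.n_dead for o in observations], dtype=float)
    X = np.column_stack([np.ones_like(t), t])
    return X, t, n, y


def _binom_deviance(y, n, p):
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(y > 0, y * np.log(y / (n * p)), 0.0)
        b = np.where(n - y > 0, (n - y) * np.log((n - y) / (n - n * p)), 0.0)
    return 2.0 * np.sum(a + b)

def _irls(X, n, y, tol: float = 1e-8, max_iter: int = 100):
    """Plain IRLS for a binomial GLM with logit link; returns (beta, cov, converged)."""
    beta = np.zeros(X.shape[1])
    # start the intercept at the empirical logit of the pooled death rate
    pbar = np.clip(y.sum() / n.sum(), 1e-6, 1 - 1e-6)
    beta[0] = math.log(pbar / (1 - pbar))
    dev = np.inf
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = n * p * (1 - p)
        if not np.all(np.isfinite(w)) or w.sum() <= 0:
            break
        z = eta + (y - n * p) / np.maximum(w, 1e-12)
        WX = X * w[:, None]
        info = X.T @ WX
        try:
            beta = np.linalg.solve(info, WX.T @ z)
        except np.linalg.LinAlgError:
            break
        new_dev = _binom_deviance(y, n, 1.0 / (1.0 + np.exp(-np.clip(X @ beta, -30, 30))))
        if abs(new_dev - dev) < tol:
            dev = new_dev
            converged = True
            break
        dev = new_dev
    eta = np.clip(X @ beta, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    info = X.T @ (X * (n * p * (1 - p))[:, None])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((2, 2), np.nan)
    return beta, cov, converged


def _firth(X, n, y, tol: float = 1e-10, max_iter: int = 200):
    """Jeffreys-prior penalized (Firth) binomial logit fit.

    The score is modified to U*(b) = X' (y - n p + h (1/2 - p)) where h are
    the leverages of the weighted hat matrix; removes the first-order bias
    and yields finite estimates under complete separation.
    """
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = n * p * (1 - p)
        WX = X * w[:, None]
        info = X.T @ WX
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            break
        # leverages of W^(1/2) X (X' W X)^-1 X' W^(1/2)
        h = np.einsum("ij,jk,ik->i", X * np.sqrt(w)[:, None], info_inv, X * np.sqrt(w)[:, None])
        score = X.T @ (y - n * p + h * (0.5 - p))
        step = info_inv @ score
        # dampen absurd steps that arise far from the optimum
        norm = np.linalg.norm(step)
        if norm > 5.0:
            step *= 5.0 / norm
        beta = beta + step
        if np.linalg.norm(step) < tol:
            break
    eta = np.clip(X @ beta, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    info = X.T @ (X * (n * p * (1 - p))[:, None])
    cov = np.linalg.inv(info)
    return beta, cov


def _is_separated(beta, cov, converged, t, n, y) -> bool:
    if not converged or not np.all(np.isfinite(cov)):
        return True
    if abs(beta[1]) > 15:  # a slope of 15 / degC is already a step function
        return True
    # quasi-separation: the slope is not distinguishable from zero because
    # the likelihood is nearly flat along a diverging direction
    if cov[1, 1] > 0 and abs(beta[1]) / math.sqrt(cov[1, 1]) < 2:
        return True
    # complete separation in dose space: a threshold splits all-alive / all-dead
    order = np.argsort(t)
    frac = (y / n)[order]
    if np.all((frac == 0) | (frac == 1)) and np.all(np.diff(frac) >= 0):
        return True
    return False


def fit_dose_response(
    observations: list[SurvivalObservation],
    tol: float = 1e-8,
    max_iter: int = 100,
) -> DoseResponseFit:
    """Fit logit(P(death)) = beta0 + beta1*T and derive LT50 with a 95% CI.

    Uses IRLS maximum likelihood; on detected complete/quasi-separation the
    fit is redone with Firth's Jeffreys-prior penalization (method="firth").
    The LT50 standard error follows from the delta method with gradient
    (-1/beta1, -lt50/beta1) applied to the coefficient covariance.
    """
    if len({o.temperature for o in observations}) < 2:
        raise ThermalFitError("need at least two distinct temperatures to fit a slope")
    X, t, n, y = _design(observations)
    if y.sum() == 0 or y.sum() == n.sum():
        raise ThermalFitError("need at least one death and one survival overall")

    beta, cov, converged = _irls(X, n, y, tol=tol, max_iter=max_iter)
    method = "ml"
    if _is_separated(beta, cov, converged, t, n, y):
        beta, cov = _firth(X, n, y)
        method = "firth"
        converged = True

    beta0, beta1 = float(beta[0]), float(beta[1])
    if beta1 == 0:
        raise ThermalFitError("zero slope: LT50 undefined")
    lt50 = -beta0 / beta1
    grad = np.array([-1.0 / beta1, -lt50 / beta1])
    var = float(grad @ cov @ grad)
    se = math.sqrt(max(var, 0.0))
    ci = (lt50 - 1.96 * se, lt50 + 1.96 * se)
    return DoseResponseFit(
        beta0=beta0,
        beta1=beta1,
        cov=cov,
        lt50=lt50,
        se_lt50=se,
        ci95=ci,
        converged=converged,
        method=method,
        n_obs=len(observations),
    )


def ratio_test(fit_a: DoseResponseFit, fit_b: DoseResponseFit) -> RatioTestResult:
    """Test H0: LT50_A / LT50_B = 1 via the log-ratio delta method.

    se(log LT50) = se(LT50)/LT50; the two fits are independent so the
    log-ratio variance is the sum, z is standard normal under H0.
    """
    if fit_a.lt50 <= 0 or fit_b.lt50 <= 0:
        raise ThermalFitError("ratio test requires positive LT50s (log undefined)")
    log_ratio = math.log(fit_a.lt50 / fit_b.lt50)
    se_log = math.sqrt(
        (fit_a.se_lt50 / fit_a.lt50) ** 2 + (fit_b.se_lt50 / fit_b.lt50) ** 2
    )
    if se_log == 0:
        z = 0.0 if log_ratio == 0 else math.inf * math.copysign(1, log_ratio)
    else:
        z = log_ratio / se_log
    p = float(2 * stats.norm.sf(abs(z))) if math.isfinite(z) else 0.0
    ci = (math.exp(log_ratio - 1.96 * se_log), math.exp(log_ratio + 1.96 * se_log))
    return RatioTestResult(
        ratio=math.exp(log_ratio), log_ratio_se=se_log, ci95=ci, z=z, p=p
    )


def _survival_groups(observations: list[SurvivalObservation]):
    temps = sorted({o.temperature for o in observations})
    groups = {
        t: np.array([o.survival for o in observations if o.temperature == t])
        for t in temps
    }
    return temps, groups


def determine_utl(observations: list[SurvivalObservation], alpha: float = 0.05) -> UTLResult:
    """Upper thermal limit: the highest assayed temperature whose survival does
    not differ significantly from the best-surviving group.

    One-way ANOVA on tube-level survival proportions, then Tukey HSD contrasts
    of every temperature against the reference group (highest mean survival,
    ties broken toward the lowest temperature).  The UTL is the highest
    temperature with adjusted p >= alpha versus the reference.
    """
    temps, groups = _survival_groups(observations)
    if len(temps) < 2:
        raise ThermalFitError("need at least two temperatures for the UTL")
    for t, g in groups.items():
        if g.size < 2:
            raise ThermalFitError(f"need >= 2 tubes per temperature (temperature {t})")

    means = {t: float(groups[t].mean()) for t in temps}
    best = max(means.values())
    reference = min(t for t in temps if means[t] == best)

    arrays = [groups[t] for t in temps]
    all_values = np.concatenate(arrays)
    k = len(temps)
    df_within = all_values.size - k
    sse = sum(float(((g - g.mean()) ** 2).sum()) for g in arrays)
    mse = sse / df_within if df_within > 0 else 0.0

    if np.ptp(all_values) == 0:
        # every tube identical: no group can differ from any other
        return UTLResult(
            utl=max(temps),
            anova_f=math.nan,
            anova_p=math.nan,
            tukey={t: 1.0 for t in temps},
            reference_temperature=reference,
            degenerate=True,
            note="all tubes identical; ANOVA undefined",
        )

    if mse == 0:
        # between-group differences with zero within-group variance
        anova_f, anova_p = math.inf, 0.0
        tukey = {t: (1.0 if means[t] == means[reference] else 0.0) for t in temps}
    else:
        anova_f, anova_p = stats.f_oneway(*arrays)
        anova_f, anova_p = float(anova_f), float(anova_p)
        tukey = {}
        n_ref = groups[reference].size
        for t in temps:
            if t == reference:
                tukey[t] = 1.0
                continue
            n_t = groups[t].size
            se = math.sqrt(mse / 2.0 * (1.0 / n_t + 1.0 / n_ref))
            q = abs(means[t] - means[reference]) / se
            tukey[t] = float(stats.studentized_range.sf(q, k, df_within))

    candidates = [t for t in temps if tukey[t] >= alpha]
    utl = max(candidates) if candidates else min(temps)
    note = "" if candidates else "every group differs from the reference"
    return UTLResult(
        utl=utl,
        anova_f=anova_f,
        anova_p=anova_p,
        tukey=tukey,
        reference_temperature=reference,
        degenerate=not candidates,
        note=note,
    )


def decline_width(
    observations: list[SurvivalObservation],
    upper: float = 0.90,
    lower: float = 0.05,
) -> DeclineWidth:
    """Width of the survival crash: distance between the highest temperature
    with mean survival >= `upper` and the lowest with mean survival <= `lower`.
    """
    temps, groups = _survival_groups(observations)
    means = {t: float(groups[t].mean()) for t in temps}
    high = [t for t in temps if means[t] >= upper]
    zero = [t for t in temps if means[t] <= lower]
    t_high = max(high) if high else None
    t_zero = min(zero) if zero else None
    if t_high is None or t_zero is None:
        missing = []
        if t_high is None:
            missing.append(f"no temperature with mean survival >= {upper}")
        if t_zero is None:
            missing.append(f"no temperature with mean survival <= {lower}")
        return DeclineWidth(t_high, t_zero, None, upper, lower, reason="; ".join(missing))
    width = t_zero - t_high
    non_monotone = width < 0
    if non_monotone:
        warnings.warn(
            "survival non-monotone: full-kill temperature below last full-survival "
            "temperature",
            stacklevel=2,
        )
    return DeclineWidth(t_high, t_zero, width, upper, lower, non_monotone=non_monotone)
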