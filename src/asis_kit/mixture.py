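"""Latent-class mixture regression of severity on age.

The cohort is modelled as a finite mixture of K linear regressions of
total severity on age: each patient (one point, usually the first visit)
belongs to a latent progression class k with probability pi_k, and within
class k the severity is Gaussian around ``intercept_k + slope_k * age``
with a residual scale shared across classes (homoscedastic by default).
The model is fit by expectation-maximisation with seeded, restartable
initialisation; classes are canonically relabelled by ascending slope.

Patients are then assigned to the nearest fitted line by vertical
(severity) distance at a chosen visit, which supports the
"category shift" analysis between first and last visits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .severity import InsufficientDataError, PatientSeries

_LOG_2PI = float(np.log(2 * np.pi))
_MIN_SIGMA = 1e-12


@dataclass
class SubgroupModel:
    """K fitted regression lines with mixture weights and a common residual scale."""

    K: int
    slopes: np.ndarray  # ascending
    intercepts: np.ndarray
    weights: np.ndarray  # simplex of length K
    residual_sd: float
    loglik: float
    seed: int
    converged: bool
    n_iter: int = 0
    loglik_trace: list[float] = field(default_factory=list)

    def predict(self, age: float | np.ndarray) -> np.ndarray:
        """Severity predicted by every class line at the given age(s)."""
        age = np.asarray(age, dtype=float)
        return self.intercepts[:, None] + self.slopes[:, None] * age[None, ...]


@dataclass(frozen=True)
class SubgroupAssignment:
    """Nearest-line class labels of one patient at first and last visit (1-based)."""

    patient_id: str
    label_first: int
    label_last: int

    @property
    def category_shift(self) -> int:
        return abs(self.label_last - self.label_first)


def _log_density(x, y, slopes, intercepts, log_weights, sigma):
    resid = y[:, None] - (intercepts[None, :] + slopes[None, :] * x[:, None])
    return log_weights[None, :] - 0.5 * (resid / sigma) ** 2 - np.log(sigma) - 0.5 * _LOG_2PI


def _m_step_line(x, y, w, zero_intercept):
    sw = w.sum()
    if sw <= 0:
        return 0.0, 0.0
    if zero_intercept:
        denom = np.sum(w * x * x)
        slope = np.sum(w * x * y) / denom if denom > 0 else 0.0
        return slope, 0.0
    xbar = np.sum(w * x) / sw
    ybar = np.sum(w * y) / sw
    sxx = np.sum(w * (x - xbar) ** 2)
    slope = np.sum(w * (x - xbar) * (y - ybar)) / sxx if sxx > 0 else 0.0
    return slope, ybar - slope * xbar


def _em_once(x, y, K, rng, tol, max_iter, zero_intercept):
    n = x.size
    # slopes seeded by jittered quantiles of per-point severity/age ratios
    ratios = y / x
    qs = np.quantile(ratios, (np.arange(K) + 0.5) / K)
    slopes = qs * rng.uniform(0.85, 1.15, size=K)
    intercepts = np.zeros(K)
    weights = np.full(K, 1.0 / K)
    resid0 = y - np.median(ratios) * x
    sigma = max(float(np.std(resid0)), 1e-2)

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        log_dens = _log_density(x, y, slopes, intercepts, np.log(weights), sigma)
        log_norm = logsumexp(log_dens, axis=1)
        ll = float(log_norm.sum())
        trace.append(ll)
        resp = np.exp(log_dens - log_norm[:, None])

        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break

        # M-step: weighted line per class, shared residual variance
        weights = resp.sum(axis=0) / n
        weights = np.clip(weights, 1e-300, None)
        weights /= weights.sum()
        for k in range(K):
            slopes[k], intercepts[k] = _m_step_line(x, y, resp[:, k], zero_intercept)
        resid = y[:, None] - (intercepts[None, :] + slopes[None, :] * x[:, None])
        sigma = float(np.sqrt(np.sum(resp * resid**2) / n))
        sigma = max(sigma, _MIN_SIGMA)

    return slopes, intercepts, weights, sigma, trace, converged, it


def fit_latent_class_lines(
    points: Sequence[tuple[float, float]],
    K: int,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
    n_restarts: int = 10,
    zero_intercept: bool = False,
) -> SubgroupModel:
    """Fit a K-class Gaussian mixture of linear regressions of severity on age by EM.

    Parameters
    ----------
    points:
        (age, severity) pairs, typically one per patient (first visit).
    K:
        Number of latent progression classes.
    seed, n_restarts:
        EM is initialisation-sensitive; ``n_restarts`` seeded starts are run
        and the best observed-data log-likelihood kept.
    zero_intercept:
        Force every class line through the origin (the ASIS construction).

    The observed-data log-likelihood is non-decreasing across EM iterations
    (``loglik_trace``).  Classes are relabelled by ascending slope.  If no
    restart converges within ``max_iter`` the best model is returned with
    ``converged=False`` and a warning.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise InsufficientDataError("mixture fit on empty data")
    x, y = pts[:, 0], pts[:, 1]
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if x.size < 2 * K:
        raise InsufficientDataError(
            f"mixture fit needs >= 2K = {2 * K} points, got {x.size}"
        )
    if np.any(x <= 0):
        raise ValueError("ages must be strictly positive")

    best = None
    for r in range(max(1, n_restarts)):
        rng = np.random.default_rng([seed, r])
        out = _em_once(x, y, K, rng, tol, max_iter, zero_intercept)
        if best is None or out[4][-1] > best[4][-1]:
            best = out
    slopes, intercepts, weights, sigma, trace, converged, n_iter = best

    order = np.argsort(slopes, kind="stable")
    model = SubgroupModel(
        K=K,
        slopes=slopes[order],
        intercepts=intercepts[order],
        weights=weights[order],
        residual_sd=sigma,
        loglik=trace[-1],
        seed=seed,
        converged=converged,
        n_iter=n_iter,
        loglik_trace=trace,
    )
    if not converged:
        warnings.warn(
            f"EM did not converge in {max_iter} iterations (K={K}, seed={seed})",
            RuntimeWarning,
        )
    return model


def assign_subgroup(series: PatientSeries, model: SubgroupModel, at: str = "first") -> int:
    """Class (1-based) whose line is vertically closest to the patient's severity.

    ``at`` selects the first or last visit.  Ties break toward the lower
    class index.
    """
    from .severity import total_severity

    if at not in ("first", "last"):
        raise ValueError(f"at must be 'first' or 'last', got {at!r}")
    visit = series.first_visit if at == "first" else series.last_visit
    sev = total_severity(visit)
    dist = np.abs(sev - model.predict(visit.age).ravel())
    return int(np.argmin(dist)) + 1


def assign_cohort(cohort: Sequence[PatientSeries], model: SubgroupModel) -> list[SubgroupAssignment]:
    """Assign every patient at first and last visit."""
    return [
        SubgroupAssignment(
            patient_id=s.patient_id,
            label_first=assign_subgroup(s, model, "first"),
            label_last=assign_subgroup(s, model, "last"),
        )
        for s in cohort
    ]


def category_shift_table(assignments: Sequence[SubgroupAssignment]) -> dict[int, int]:
    """Histogram of |label_last - label_first| over patients; values sum to n."""
    table: dict[int, int] = {}
    for a in assignments:
        table[a.category_shift] = table.get(a.category_shift, 0) + 1
    return table
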