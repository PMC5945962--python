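"""Normal/abnormal event distributions per biomarker.

Each biomarker's "event" is its transition from a normal to an abnormal
distribution.  The normal model P(x|not-E) is a Gaussian fitted to control
values; the abnormal model P(x|E) is the free component of a two-Gaussian
mixture fitted to patient values by EM with the control component's
parameters held fixed.  Holding the control component fixed is what makes the
fit identifiable with modest sample sizes: controls are genetically
determined here, so the normal distribution can be estimated separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "GaussianParams",
    "EventDistributionFit",
    "EventLikelihoodTable",
    "fit_control_model",
    "fit_patient_mixture",
    "fit_all_biomarkers",
    "event_likelihoods",
    "abnormality_threshold",
]


class GaussianParams(NamedTuple):
    mean: float
    sd: float

    def logpdf(self, x) -> np.ndarray:
        return norm.logpdf(x, self.mean, self.sd)


@dataclass(frozen=True)
class EventDistributionFit:
    """Mixture fit for one biomarker: fixed normal component, fitted abnormal
    component, and the fraction of patient values attributed to the abnormal
    component."""

    normal: GaussianParams
    abnormal: GaussianParams
    mixing_weight: float
    converged: bool
    n_iterations: int
    log_likelihood: float = float("nan")


def fit_control_model(control_values) -> GaussianParams:
    """Maximum-likelihood Gaussian for the control (normal) distribution.

    Uses the ML variance (``ddof=0``); e.g. values ``{-1, 0, 1}`` give mean 0
    and SD ``sqrt(2/3)``.
    """
    x = np.asarray(control_values, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 control values")
    sd = float(x.std(ddof=0))
    if sd <= 0:
        raise ValueError("control values have degenerate (zero) variance")
    return GaussianParams(float(x.mean()), sd)


def fit_patient_mixture(patient_values, normal: GaussianParams, *,
                        max_iter: int = 500, tol: float = 1e-6,
                        sd_floor_frac: float = 0.05,
                        weight_bounds: tuple[float, float] = (0.01, 0.99),
                        ) -> EventDistributionFit:
    """EM fit of the patient mixture with the normal component fixed.

    Free parameters: abnormal mean, abnormal SD, mixing weight (fraction
    abnormal).  Initialisation is deterministic: EM is run from the patient
    sample moments and from the moments of the patient values lying on the
    abnormal side of the control mean (a single wide start can absorb both
    clusters into one component — a local optimum — which the split start
    avoids), keeping the solution with the higher likelihood.  The abnormal
    SD is floored at ``sd_floor_frac`` x the control SD (narrow abnormal
    components are legitimate, density blow-up is not); the weight is clipped
    to ``weight_bounds`` so both likelihood channels stay defined.
    """
    x = np.asarray(patient_values, dtype=float)
    if x.size < 5:
        raise ValueError("need >= 5 patient values")
    sd_floor = sd_floor_frac * normal.sd
    log_n = normal.logpdf(x)

    def loglik(m, s, w):
        la = norm.logpdf(x, m, s) + np.log(w)
        ln = log_n + np.log1p(-w)
        return float(np.logaddexp(la, ln).sum())

    def run_em(ab_mean: float, ab_sd: float, w: float):
        ab_sd = max(ab_sd, sd_floor)
        prev = loglik(ab_mean, ab_sd, w)
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            # E-step: responsibility of the abnormal component
            la = norm.logpdf(x, ab_mean, ab_sd) + np.log(w)
            ln = log_n + np.log1p(-w)
            r = np.exp(la - np.logaddexp(la, ln))
            # M-step
            rsum = r.sum()
            w = float(np.clip(rsum / x.size, *weight_bounds))
            if rsum > 0:
                ab_mean = float((r * x).sum() / rsum)
                ab_sd = max(float(np.sqrt((r * (x - ab_mean) ** 2).sum() / rsum)),
                            sd_floor)
            cur = loglik(ab_mean, ab_sd, w)
            if abs(cur - prev) < tol:
                converged = True
                prev = cur
                break
            prev = cur
        return EventDistributionFit(normal, GaussianParams(ab_mean, ab_sd),
                                    w, converged, it, prev)

    starts = [(float(x.mean()), float(x.std(ddof=0)), 0.5)]
    side = np.sign(x.mean() - normal.mean) or -1.0
    split = x[np.sign(x - normal.mean) == side]
    if split.size >= 2 and split.size < x.size:
        starts.append((float(split.mean()), float(split.std(ddof=0)), 0.5))
    best = max((run_em(*s) for s in starts), key=lambda f: f.log_likelihood)
    if not best.converged:
        warnings.warn("patient mixture EM did not converge within "
                      f"{max_iter} iterations", stacklevel=2)
    return best


def fit_all_biomarkers(matrix, control_label: str = "HC",
                       patient_label: str = "HD", **em_kwargs,
                       ) -> dict[str, EventDistributionFit]:
    """Fit control model + patient mixture for every biomarker column of a
    BiomarkerMatrix.  Only the two named groups enter the fits."""
    fits = {}
    hc = matrix.group(control_label)
    hd = matrix.group(patient_label)
    for name in matrix.biomarker_names:
        normal = fit_control_model(hc[name].to_numpy())
        fits[name] = fit_patient_mixture(hd[name].to_numpy(), normal, **em_kwargs)
    return fits


@dataclass
class EventLikelihoodTable:
    """Log-densities of every observation under both components.

    ``log_p_event[j, i]`` and ``log_p_not_event[j, i]`` are log P(x_ij|E_i)
    and log P(x_ij|not-E_i) for subject j, biomarker i.
    """

    log_p_event: np.ndarray
    log_p_not_event: np.ndarray
    biomarker_names: list[str]
    subject_ids: list

    def __post_init__(self) -> None:
        self.log_p_event = np.asarray(self.log_p_event, dtype=float)
        self.log_p_not_event = np.asarray(self.log_p_not_event, dtype=float)
        if self.log_p_event.shape != self.log_p_not_event.shape:
            raise ValueError("log-density arrays must have identical shape")
        if not (np.isfinite(self.log_p_event).all()
                and np.isfinite(self.log_p_not_event).all()):
            raise ValueError("log-densities must be finite")

    @property
    def n_subjects(self) -> int:
        return self.log_p_event.shape[0]

    @property
    def n_biomarkers(self) -> int:
        return self.log_p_event.shape[1]


def event_likelihoods(matrix, fits: dict[str, EventDistributionFit],
                      ) -> EventLikelihoodTable:
    """Evaluate both component log-densities for every subject x biomarker."""
    names = matrix.biomarker_names
    missing = [n for n in names if n not in fits]
    if missing:
        raise ValueError(f"no distribution fit for biomarkers {missing}")
    x = matrix.values.to_numpy(dtype=float)
    lpe = np.empty_like(x)
    lpn = np.empty_like(x)
    for i, name in enumerate(names):
        f = fits[name]
        lpe[:, i] = f.abnormal.logpdf(x[:, i])
        lpn[:, i] = f.normal.logpdf(x[:, i])
    return EventLikelihoodTable(lpe, lpn, list(names), matrix.subject_ids)


def abnormality_threshold(fit: EventDistributionFit) -> float:
    """The value where a measurement is equally likely normal or abnormal.

    Solves ``N(x; m1, s1) = N(x; m2, s2)`` — a quadratic in x — and returns
    the root between the two component means.  With equal SDs this is the
    midpoint.  If no root lies strictly between the means (possible when the
    SDs differ greatly), the root closest to the midpoint is returned.
    """
    m1, s1 = fit.normal
    m2, s2 = fit.abnormal
    if np.isclose(m1, m2) and np.isclose(s1, s2):
        raise ValueError("components are identical; threshold undefined")
    if np.isclose(s1, s2):
        return 0.5 * (m1 + m2)
    a = 1.0 / s2**2 - 1.0 / s1**2
    b = -2.0 * (m2 / s2**2 - m1 / s1**2)
    c = m2**2 / s2**2 - m1**2 / s1**2 - 2.0 * np.log(s1 / s2)
    disc = b * b - 4 * a * c
    if disc < 0:
        raise ValueError("no real density crossing between the components")
    roots = np.array([(-b - np.sqrt(disc)) / (2 * a), (-b + np.sqrt(disc)) / (2 * a)])
    lo, hi = sorted((m1, m2))
    between = roots[(roots >= lo) & (roots <= hi)]
    if between.size:
        return float(between[0])
    mid = 0.5 * (m1 + m2)
    return float(roots[np.argmin(np.abs(roots - mid))])
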