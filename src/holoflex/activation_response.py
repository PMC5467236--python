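"""Variable-slope dose-response (Hill) simulation and fitting.

The four-parameter logistic in log dose,

    y(c) = bottom + (top - bottom) / (1 + (EC50 / c)^n),

describes cooperative activation; n (the Hill coefficient) > 1 indicates
positive cooperativity.  Fitting is done by nonlinear least squares in
log10-dose.  The module is exercised as parameter recovery on synthetic
data; utilities compare two fits by EC50 fold change and Hill-coefficient
difference with delta-method standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "FitError",
    "UnidentifiableError",
    "HillParameters",
    "HillFit",
    "DoseResponse",
    "hill_curve",
    "simulate_dose_response",
    "fit_hill",
    "fold_change",
]


class FitError(RuntimeError):
    """Nonlinear fit failed to converge."""


class UnidentifiableError(FitError):
    """Flat data: parameters not identifiable."""


@dataclass(frozen=True)
class HillParameters:
    bottom: float
    top: float
    ec50: float              # concentration; units carried by the data
    hill_n: float

    def validate(self) -> None:
        if not self.top > self.bottom:
            raise ValueError("top must exceed bottom")
        if self.ec50 <= 0:
            raise ValueError("ec50 must be positive")
        if self.hill_n <= 0:
            raise ValueError("hill_n must be positive")


@dataclass
class HillFit:
    params: HillParameters
    stderr: dict                       # parameter name -> s.e.
    covariance: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        p = self.params
        return {"bottom": p.bottom, "top": p.top, "ec50": p.ec50,
                "hill_n": p.hill_n, "stderr": dict(self.stderr)}


@dataclass
class DoseResponse:
    concentrations: np.ndarray
    responses: np.ndarray
    replicates: np.ndarray | None = None

    def validate(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        if c.shape != r.shape:
            raise ValueError("length mismatch")
        if (c <= 0).any():
            raise ValueError("concentrations must be positive")


def hill_curve(c, bottom: float, top: float, ec50: float,
               hill_n: float):
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ec50 / c) ** hill_n)


def _logistic_logdose(logc, bottom, top, log_ec50, hill_n):
    return bottom + (top - bottom) / (1.0 + 10 ** (hill_n * (log_ec50 - logc)))


def simulate_dose_response(params: HillParameters, doses: Sequence[float],
                           noise_cv: float = 0.0,
                           seed: int = 0) -> DoseResponse:
    """Responses on the Hill curve with multiplicative Gaussian noise."""
    params.validate()
    c = np.asarray(doses, dtype=float)
    y = hill_curve(c, params.bottom, params.top, params.ec50, params.hill_n)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        y = y * (1.0 + rng.normal(0.0, noise_cv, y.shape))
    dr = DoseResponse(concentrations=c, responses=y)
    dr.validate()
    return dr


def fit_hill(data: DoseResponse) -> HillFit:
    """Least-squares 4-parameter logistic fit in log10-dose.

    For monotone-decreasing data the fit converges with a negative Hill
    slope (sign convention: hill_n > 0 for activation, < 0 for
    inhibition).  Standard errors come from the fit covariance; the EC50
    s.e. is propagated from log10(EC50) by the delta method.
    """
    data.validate()
    c = np.asarray(data.concentrations, dtype=float)
    y = np.asarray(data.responses, dtype=float)
    if len(np.unique(c)) < 5:
        raise FitError("need at least 5 distinct doses")
    span = y.max() - y.min()
    if span < 1e-12 * max(1.0, abs(y).max()):
        raise UnidentifiableError("flat response data")

    logc = np.log10(c)
    p0 = (float(y.min()), float(y.max()), float(np.median(logc)), 1.0)
    try:
        popt, pcov = curve_fit(_logistic_logdose, logc, y, p0=p0,
                               maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - rare
        raise FitError(f"Hill fit did not converge: {exc}") from exc

    bottom, top, log_ec50, hill_n = popt
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    if top < bottom:
        # the 4PL is invariant under (bottom, top, n) -> (top, bottom, -n);
        # normalise to top > bottom so the slope sign carries the direction
        bottom, top = top, bottom
        hill_n = -hill_n
        perr = perr[[1, 0, 2, 3]]
    ec50 = 10.0 ** log_ec50
    # d(ec50)/d(log_ec50) = ln(10) * ec50
    ec50_se = float(np.log(10.0) * ec50 * perr[2])
    params = HillParameters(bottom=float(bottom), top=float(top),
                            ec50=float(ec50), hill_n=float(hill_n))
    stderr = {"bottom": float(perr[0]), "top": float(perr[1]),
              "ec50": ec50_se, "hill_n": float(perr[3])}
    return HillFit(params=params, stderr=stderr, covariance=pcov)


def fold_change(fit_a: HillFit, fit_b: HillFit) -> dict:
    """EC50 ratio (b/a) and Hill difference (b-a) with delta-method s.e."""
    a, b = fit_a.params, fit_b.params
    ratio = b.ec50 / a.ec50
    rel_a = fit_a.stderr["ec50"] / a.ec50
    rel_b = fit_b.stderr["ec50"] / b.ec50
    ratio_se = ratio * float(np.hypot(rel_a, rel_b))
    diff = b.hill_n - a.hill_n
    diff_se = float(np.hypot(fit_a.stderr["hill_n"],
                             fit_b.stderr["hill_n"]))
    return {"ec50_ratio": ratio, "ec50_ratio_se": ratio_se,
            "hill_difference": diff, "hill_difference_se": diff_se}
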