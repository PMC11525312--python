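"""Five-parameter logistic dose-response fitting and ED_x estimation.

Replicate integrals are normalized to the global maximum across all
replicates and doses, averaged per dose, and fitted with the asymmetric
logistic

    f(x) = d + (a - d) / (1 + (x / w)^b)^f

with bottom plateau d, top plateau a, inflection w, slope b and symmetry
factor f. ED_x (the dose producing x % of the maximal effect) follows from
the closed-form inversion; confidence intervals use the delta method on
the log-dose scale with the parameter covariance from the least-squares
fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import t as t_dist

from .errors import DataError, RangeError
from .fixtures import fivepl


@dataclass
class DoseResponseData:
    """Raw replicate responses per dose."""

    doses: np.ndarray
    responses: np.ndarray
    replicates: np.ndarray

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, float)
        self.responses = np.asarray(self.responses, float)
        self.replicates = np.asarray(self.replicates)
        if not (len(self.doses) == len(self.responses) == len(self.replicates)):
            raise DataError("doses, responses and replicates must be equal length")
        if np.any(self.doses <= 0):
            raise DataError("doses must be positive")

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, response_col: str = "response"
    ) -> "DoseResponseData":
        return cls(
            df["dose"].to_numpy(float),
            df[response_col].to_numpy(float),
            df["replicate"].to_numpy(),
        )


def normalize_and_average(data: DoseResponseData) -> pd.DataFrame:
    """Normalize to the global maximum and average per dose.

    Every response is divided by the maximum across all replicates and
    doses; the table reports the per-dose mean with a t-based 95 %
    confidence interval of the mean. Normalizing twice changes nothing.
    """
    peak = float(np.max(data.responses))
    if peak <= 0:
        raise DataError("all responses are non-positive; cannot normalize")
    norm = data.responses / peak
    df = pd.DataFrame({"dose": data.doses, "norm": norm})
    rows = []
    for dose, grp in df.groupby("dose"):
        v = grp.norm.to_numpy()
        m = float(np.mean(v))
        if len(v) > 1:
            half = float(t_dist.ppf(0.975, len(v) - 1) * np.std(v, ddof=1) / np.sqrt(len(v)))
        else:
            half = np.nan
        rows.append({"dose": float(dose), "mean_response": m, "ci95_half": half, "n": len(v)})
    return pd.DataFrame(rows).sort_values("dose", ignore_index=True)


@dataclass
class DoseResponseFit:
    """Fitted 5PL parameters with covariance."""

    a: float
    d: float
    w: float
    b: float
    f: float
    covariance: np.ndarray
    df: int = 0  # residual degrees of freedom of the fit
    status: str = "converged"
    message: str = ""

    @property
    def params(self) -> np.ndarray:
        return np.array([self.a, self.d, self.w, self.b, self.f])

    def predict(self, doses) -> np.ndarray:
        return fivepl(doses, self.a, self.d, self.w, self.b, self.f)


def fit_5pl(series: pd.DataFrame) -> DoseResponseFit:
    """Least-squares 5PL fit to a (dose, mean_response) series.

    Initialization from the data: d = min, a = max, w = the dose nearest
    the half-range response, slope from the log-dose gradient, f = 1.
    Non-convergence yields ``status='failed'`` with diagnostics rather than
    an exception.
    """
    doses = series["dose"].to_numpy(float)
    resp = series["mean_response"].to_numpy(float)
    if len(np.unique(doses)) < 5:
        raise DataError("5PL fitting needs at least 5 distinct doses")
    d0, a0 = float(np.min(resp)), float(np.max(resp))
    half = (a0 + d0) / 2.0
    w0 = float(doses[np.argmin(np.abs(resp - half))])
    # crude slope sign/magnitude from the response trend on log-dose
    trend = np.polyfit(np.log(doses), resp, 1)[0]
    b0 = -2.0 if trend > 0 else 2.0
    p0 = [a0, d0 if a0 > d0 else d0 - 1e-6, w0, b0, 1.0]
    lo = [-np.inf, -np.inf, 1e-12, -50.0, 1e-6]
    hi = [np.inf, np.inf, np.inf, 50.0, 50.0]
    try:
        popt, pcov = curve_fit(
            fivepl, doses, resp, p0=p0, bounds=(lo, hi), maxfev=20000, xtol=1e-10
        )
    except (RuntimeError, ValueError) as exc:
        return DoseResponseFit(
            np.nan, np.nan, np.nan, np.nan, np.nan,
            covariance=np.full((5, 5), np.nan),
            status="failed",
            message=str(exc),
        )
    return DoseResponseFit(*popt, covariance=pcov, df=max(len(doses) - 5, 1))


def _ed_from_params(theta: np.ndarray, x_percent: float) -> float:
    a, d, w, b, f = theta
    return w * ((100.0 / x_percent) ** (1.0 / f) - 1.0) ** (1.0 / b)


@dataclass(frozen=True)
class EDx:
    x_percent: float
    dose: float
    ci_low: float
    ci_high: float

    @property
    def ci95_half(self) -> float:
        return (self.ci_high - self.ci_low) / 2.0


def ed_x(fit: DoseResponseFit, x_percent: float) -> EDx:
    """Dose producing x % of the maximal effect, with a 95 % CI.

    The dose solves f(dose) = d + (x/100)(a - d) in closed form:
    dose = w ((100/x)^(1/f) - 1)^(1/b). The confidence interval is a delta-
    method interval on the log-dose scale, propagated from the parameter
    covariance, with a t critical value at the fit's residual degrees of
    freedom (dose-response series are short, so the normal quantile would
    understate the uncertainty). For f = 1 and x = 50 the dose equals the
    inflection w.
    """
    if fit.status != "converged" or not np.isfinite(fit.w):
        raise DataError("ED_x requires a converged dose-response fit")
    if not 0 < x_percent < 100:
        raise RangeError("x_percent must lie strictly between 0 and 100")
    theta = fit.params
    dose = _ed_from_params(theta, x_percent)
    if not np.isfinite(dose) or dose <= 0:
        raise RangeError("target effect outside the fitted range")
    # numerical gradient of log(ED) w.r.t. the parameters
    grad = np.zeros(5)
    for k in range(5):
        h = max(abs(theta[k]), 1e-3) * 1e-6
        up, dn = theta.copy(), theta.copy()
        up[k] += h
        dn[k] -= h
        e_up, e_dn = _ed_from_params(up, x_percent), _ed_from_params(dn, x_percent)
        if e_up <= 0 or e_dn <= 0 or not (np.isfinite(e_up) and np.isfinite(e_dn)):
            grad[k] = 0.0
        else:
            grad[k] = (np.log(e_up) - np.log(e_dn)) / (2 * h)
    var_log = float(grad @ fit.covariance @ grad)
    var_log = max(var_log, 0.0)
    se = np.sqrt(var_log)
    crit = float(t_dist.ppf(0.975, fit.df)) if fit.df > 0 else 1.959963984540054
    return EDx(
        x_percent=float(x_percent),
        dose=float(dose),
        ci_low=float(dose * np.exp(-crit * se)),
        ci_high=float(dose * np.exp(crit * se)),
    )
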