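"""Concentration-response analysis with the modified Hill equation.

Neomycin screens the charges of PIP2 and thereby blocks PIP2-dependent
channel current; the concentration dependence of the remaining current
reports on the channel's PIP2 affinity.  Currents normalized to the control
current follow

    I / I_c = a + (1 - a) / (1 + ([X] / IC50)^h)

where IC50 is the half-maximal inhibitory concentration, h the Hill slope
and ``a`` the fraction of unblocked current at saturating blocker.  Fitting
is done by least squares in log10-concentration space, the standard
convention for sigmoid dose-response curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "HillParams",
    "DoseResponseData",
    "HillFitResult",
    "hill_response",
    "fit_hill",
    "control_current",
    "simulate_dose_response",
]


@dataclass(frozen=True)
class HillParams:
    """Parameters of the modified Hill equation."""

    ic50: float  # M
    h: float  # dimensionless, > 0
    a: float = 0.0  # unblocked fraction in [0, 1]

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ValueError("IC50 must be > 0")
        if self.h <= 0:
            raise ValueError("Hill slope must be > 0")
        if not 0.0 <= self.a <= 1.0:
            raise ValueError("unblocked fraction a must be in [0, 1]")


@dataclass
class DoseResponseData:
    """Concentrations (M) with normalized currents I/I_c."""

    concentrations: np.ndarray
    responses: np.ndarray
    se: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise ValueError("concentrations and responses must align")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be > 0")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("responses must be finite")


@dataclass
class HillFitResult:
    """Fitted parameters with standard errors from the fit covariance."""

    params: HillParams
    se_ic50: float
    se_h: float
    se_a: float
    rss: float
    converged: bool = True


def hill_response(X, params: HillParams):
    """Normalized current at concentration(s) ``X`` (M)."""
    X = np.asarray(X, dtype=float)
    if np.any(X <= 0):
        raise ValueError("concentrations must be > 0")
    out = params.a + (1.0 - params.a) / (1.0 + (X / params.ic50) ** params.h)
    return float(out) if out.ndim == 0 else out


def _model_log10(logx, log_ic50, h, a):
    return a + (1.0 - a) / (1.0 + 10.0 ** (h * (logx - log_ic50)))


def fit_hill(
    data: DoseResponseData,
    init: HillParams | None = None,
    fix_a: float | None = None,
) -> HillFitResult:
    """Least-squares Hill fit in log10-concentration space.

    Bounds: IC50 > 0 (fitted as log10 IC50), h > 0, a in [0, 1].
    ``fix_a`` pins the unblocked fraction (e.g. 0 for constructs that close
    completely at saturating blocker).  Needs at least as many distinct
    concentrations as free parameters.
    """
    x = data.concentrations
    y = data.responses
    n_free = 2 if fix_a is not None else 3
    if np.unique(x).size < n_free:
        raise ValueError(
            f"need >= {n_free} distinct concentrations for {n_free} free parameters"
        )
    logx = np.log10(x)
    if init is None:
        # IC50 guess: concentration whose response is nearest half-way
        a0 = float(np.clip(np.min(y), 0.0, 1.0)) if fix_a is None else fix_a
        half = a0 + (1.0 - a0) / 2.0
        ic0 = float(x[np.argmin(np.abs(y - half))])
        init = HillParams(ic50=ic0, h=1.0, a=a0)
    p0 = [np.log10(init.ic50), init.h, init.a]

    if fix_a is not None:
        def model(lx, lic, h):
            return _model_log10(lx, lic, h, fix_a)
        p0 = p0[:2]
        lb, ub = [-np.inf, 1e-12], [np.inf, np.inf]
    else:
        model = _model_log10
        lb, ub = [-np.inf, 1e-12, 0.0], [np.inf, np.inf, 1.0]

    converged = True
    try:
        popt, pcov = curve_fit(
            model, logx, y, p0=p0, bounds=(lb, ub), maxfev=20000
        )
    except RuntimeError:
        warnings.warn("Hill fit did not converge")
        popt, pcov = np.array(p0), np.full((len(p0), len(p0)), np.nan)
        converged = False

    perr = np.sqrt(np.diag(pcov))
    ic50 = 10.0 ** popt[0]
    h = popt[1]
    a = fix_a if fix_a is not None else popt[2]
    se_a = 0.0 if fix_a is not None else float(perr[2])
    # delta method: SE(IC50) = ln(10) * IC50 * SE(log10 IC50)
    se_ic50 = float(np.log(10.0) * ic50 * perr[0])
    fitted = model(logx, *popt)
    rss = float(np.sum((y - fitted) ** 2))
    return HillFitResult(
        params=HillParams(ic50=float(ic50), h=float(h), a=float(np.clip(a, 0, 1))),
        se_ic50=se_ic50,
        se_h=float(perr[1]),
        se_a=se_a,
        rss=rss,
        converged=converged,
    )


def control_current(pre_value: float | None, post_value: float | None) -> float:
    """Control current I_c: mean of the bracketing control measurements.

    If only one bracket is available that value is used, with a warning that
    channel rundown is not accounted for.
    """
    if pre_value is None and post_value is None:
        raise ValueError("at least one control measurement is required")
    if pre_value is None or post_value is None:
        warnings.warn("control current not bracketed; rundown unaccounted for")
        return float(pre_value if pre_value is not None else post_value)
    return 0.5 * (float(pre_value) + float(post_value))


def simulate_dose_response(
    params: HillParams,
    concentrations,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DoseResponseData:
    """Synthetic concentration-response data: Hill curve plus Gaussian noise.

    With ``noise_sd = 0`` the data reproduce the curve exactly; identical
    seeds give identical data.
    """
    x = np.asarray(concentrations, dtype=float)
    if np.any(x <= 0):
        raise ValueError("concentrations must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    y = hill_response(x, params)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + noise_sd * rng.standard_normal(x.shape)
    return DoseResponseData(concentrations=x, responses=np.asarray(y, dtype=float))
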