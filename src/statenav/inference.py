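"""From measured curves to state-specific dissociation constants.

The analysis chain mirrors the standard modulated-receptor workflow:

1. fit control and drug availability curves with a Boltzmann function;
2. correct the raw midpoint shift for the slow time-dependent drift seen in
   drug-free recordings (corrected = raw - control drift);
3. convert the resting-state block ``b`` (fraction of current remaining at a
   strongly hyperpolarized holding potential) into K_r = D*b/(1-b);
4. invert the coupled-equilibrium shift equation for the inactivated-state
   constant: K_i = D / [(1 + D/K_r) * exp(|dV|/k) - 1].

Dose-inhibition data are fitted with a Hill function
``inhibition = 1 / (1 + (IC50/D)^n)``.

Both fits run scipy's trust-region-reflective least squares with bounds and
record the per-iteration objective, which is non-increasing (accepted trust
region steps only ever lower the cost).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .model import BoltzmannParams, StateBindingModel

__all__ = [
    "AvailabilityCurve",
    "DoseResponseCurve",
    "BoltzmannFitResult",
    "HillFitResult",
    "ShiftAnalysis",
    "fit_boltzmann",
    "fit_hill",
    "drift_corrected_shift",
    "infer_kd_rest",
    "infer_kd_inact",
    "analyze_state_dependence",
]

SLOPE_BOUNDS = (0.5, 30.0)   # mV, plausible range for Nav inactivation
HILL_N_BOUNDS = (0.2, 5.0)


@dataclass
class AvailabilityCurve:
    """Prepulse voltage vs. normalized peak test-pulse current."""

    prepulse_v: np.ndarray
    current_norm: np.ndarray
    prepulse_duration: float = 5000.0  # ms; 5000 = steady state, 50 = fast
    test_v: float = 10.0
    drug_conc: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.prepulse_v = np.asarray(self.prepulse_v, dtype=float)
        self.current_norm = np.asarray(self.current_norm, dtype=float)
        if self.prepulse_v.shape != self.current_norm.shape:
            raise ValueError("voltage and current arrays must have equal length")
        if self.prepulse_v.size < 5:
            raise ValueError("need at least 5 points for an availability curve")
        if not np.all(np.isfinite(self.current_norm)):
            raise ValueError("currents must be finite")
        if np.any(self.current_norm < 0):
            raise ValueError("normalized currents must be >= 0")


@dataclass
class DoseResponseCurve:
    """Drug concentration (nM) vs. fractional inhibition."""

    conc: np.ndarray
    inhibition: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        self.inhibition = np.asarray(self.inhibition, dtype=float)
        if self.conc.shape != self.inhibition.shape:
            raise ValueError("concentration and inhibition arrays must match")
        if self.conc.size < 3:
            raise ValueError("need at least 3 concentrations")
        if np.any(self.conc <= 0):
            raise ValueError("concentrations must be positive")
        if np.any((self.inhibition < 0) | (self.inhibition > 1)):
            raise ValueError("inhibition must lie in [0, 1]")


@dataclass
class BoltzmannFitResult:
    params: BoltzmannParams
    rss: float
    converged: bool
    stderr: dict[str, float] = field(default_factory=dict)
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class HillFitResult:
    ic50: float           # nM
    hill_n: float
    rss: float
    converged: bool
    stderr: dict[str, float] = field(default_factory=dict)
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class ShiftAnalysis:
    """End-to-end result of the state-dependence analysis."""

    control_fit: BoltzmannFitResult
    drug_fit: BoltzmannFitResult
    raw_shift: float
    control_drift: float
    corrected_shift: float
    kd_rest: float
    kd_inact: float


def _stderr(res, names) -> dict[str, float]:
    """Parameter standard errors from the fit's J^T J covariance."""
    dof = res.fun.size - res.x.size
    if dof <= 0:
        return {}
    try:
        cov = np.linalg.inv(res.jac.T @ res.jac) * (2 * res.cost / dof)
    except np.linalg.LinAlgError:
        return {}
    d = np.sqrt(np.clip(np.diag(cov), 0, None))
    return dict(zip(names, d.tolist()))


def fit_boltzmann(curve: AvailabilityCurve) -> BoltzmannFitResult:
    """Least-squares Boltzmann fit of an availability curve.

    Initialization: midpoint from the linearly interpolated half-maximum
    crossing, slope 8 mV, amplitude = max.  On noiseless Boltzmann input the
    generating parameters are recovered to ~1e-6 relative.  Degenerate input
    (no spread, or slope pinned at its bounds) is flagged ``converged=False``
    rather than silently returned.
    """
    v = curve.prepulse_v
    y = curve.current_norm
    amp0 = float(y.max())
    if amp0 <= 0 or np.ptp(y) < 1e-12 * max(1.0, amp0):
        return BoltzmannFitResult(
            BoltzmannParams(float(np.median(v)), 8.0, amp0 or 1.0),
            rss=float(np.sum((y - y.mean()) ** 2)),
            converged=False,
        )
    # half-max crossing (curve is decreasing in v)
    half = amp0 / 2.0
    idx = np.where(y <= half)[0]
    if idx.size and idx[0] > 0:
        i = idx[0]
        f = (half - y[i - 1]) / (y[i] - y[i - 1])
        v0 = float(v[i - 1] + f * (v[i] - v[i - 1]))
    else:
        v0 = float(np.median(v))

    trace: list[float] = []

    def resid(p):
        vh, k, a = p
        return a / (1.0 + np.exp((v - vh) / k)) - y

    def cb(intermediate_result):
        trace.append(float(intermediate_result.cost))

    res = least_squares(
        resid,
        x0=[v0, 8.0, amp0],
        bounds=([v.min() - 200.0, SLOPE_BOUNDS[0], 0.0],
                [v.max() + 200.0, SLOPE_BOUNDS[1], 10.0]),
        method="trf",
        ftol=1e-14, xtol=1e-14, gtol=1e-14,
        max_nfev=500,
        callback=cb,
    )
    vh, k, a = res.x
    at_bounds = (
        k <= SLOPE_BOUNDS[0] * (1 + 1e-6) or k >= SLOPE_BOUNDS[1] * (1 - 1e-6)
    )
    converged = bool(res.success) and not at_bounds
    return BoltzmannFitResult(
        BoltzmannParams(float(vh), float(k), float(a)),
        rss=float(2 * res.cost),
        converged=converged,
        stderr=_stderr(res, ("v_half", "slope", "amplitude")),
        objective_trace=np.asarray(trace),
    )


def fit_hill(curve: DoseResponseCurve, fix_n: float | None = None) -> HillFitResult:
    """Least-squares Hill fit: inhibition = 1 / (1 + (IC50/D)^n).

    The IC50 is fitted on a log10 scale (well conditioned across decades);
    the Hill coefficient is free by default or can be fixed (``fix_n``).
    All-zero inhibition is flagged non-converged.
    """
    d = curve.conc
    y = curve.inhibition
    if np.all(y < 1e-12):
        return HillFitResult(
            ic50=float(np.sqrt(d.min() * d.max())), hill_n=1.0,
            rss=float(np.sum(y**2)), converged=False,
        )
    logd = np.log10(d)
    # IC50 init from log-linear interpolation at half inhibition
    idx = np.where(y >= 0.5)[0]
    if idx.size and idx[0] > 0:
        i = idx[0]
        f = (0.5 - y[i - 1]) / (y[i] - y[i - 1])
        p0 = float(logd[i - 1] + f * (logd[i] - logd[i - 1]))
    else:
        p0 = float(np.median(logd))

    trace: list[float] = []

    def model(logc50, n):
        return 1.0 / (1.0 + 10.0 ** (n * (logc50 - logd)))

    def cb(intermediate_result):
        trace.append(float(intermediate_result.cost))

    if fix_n is None:
        def resid(p):
            return model(p[0], p[1]) - y
        x0 = [p0, 1.0]
        lb = [logd.min() - 6.0, HILL_N_BOUNDS[0]]
        ub = [logd.max() + 6.0, HILL_N_BOUNDS[1]]
    else:
        def resid(p):
            return model(p[0], fix_n) - y
        x0 = [p0]
        lb = [logd.min() - 6.0]
        ub = [logd.max() + 6.0]

    res = least_squares(
        resid, x0=x0, bounds=(lb, ub), method="trf",
        ftol=1e-14, xtol=1e-14, gtol=1e-14, max_nfev=500, callback=cb,
    )
    logc50 = float(res.x[0])
    n_hat = float(res.x[1]) if fix_n is None else float(fix_n)
    ic50 = 10.0 ** logc50
    at_bounds = fix_n is None and (
        n_hat <= HILL_N_BOUNDS[0] * (1 + 1e-6) or n_hat >= HILL_N_BOUNDS[1] * (1 - 1e-6)
    )
    converged = bool(res.success) and not at_bounds
    err = _stderr(res, ("log10_ic50", "hill_n") if fix_n is None else ("log10_ic50",))
    if "log10_ic50" in err:
        err["ic50"] = ic50 * math.log(10) * err["log10_ic50"]
    return HillFitResult(
        ic50=ic50, hill_n=n_hat, rss=float(2 * res.cost),
        converged=converged, stderr=err, objective_trace=np.asarray(trace),
    )


def drift_corrected_shift(raw_shift: float, control_drift: float) -> float:
    """Subtract the time-dependent control drift from a raw midpoint shift.

    Availability midpoints drift slowly hyperpolarized during long
    whole-cell recordings even without drug; the drug-attributable shift is
    the raw shift minus the average drift measured in control solution over
    the same period.
    """
    if not (np.isfinite(raw_shift) and np.isfinite(control_drift)):
        raise ValueError("shift inputs must be finite")
    return raw_shift - control_drift


def infer_kd_rest(resting_block: float, drug_conc: float) -> float:
    """Resting-state dissociation constant from hyperpolarized block.

    One-site occupancy: a remaining-current fraction ``b`` at a voltage where
    all channels are resting implies K_r = D*b/(1-b).  ``b = 1`` (no block)
    returns ``math.inf`` explicitly.
    """
    if not (0.0 < resting_block <= 1.0):
        raise ValueError(f"resting_block must lie in (0, 1], got {resting_block}")
    if drug_conc <= 0:
        raise ValueError("drug_conc must be positive")
    if resting_block == 1.0:
        return math.inf
    return drug_conc * resting_block / (1.0 - resting_block)


def infer_kd_inact(
    corrected_shift: float, slope: float, drug_conc: float, kd_rest: float
) -> float:
    """Invert the coupled-equilibrium shift for the inactivated-state K_d.

    K_i = D / [(1 + D/K_r) * exp(|dV|/k) - 1].  A zero shift returns K_r
    (equal affinities).  If the bracket is non-positive — the shift is too
    small (or depolarizing) to be explained by any K_i <= K_r — a ValueError
    carrying a no-binding diagnostic is raised.
    """
    if slope <= 0:
        raise ValueError("slope must be positive")
    if drug_conc <= 0:
        raise ValueError("drug_conc must be positive")
    if corrected_shift > 0:
        raise ValueError(
            "corrected shift is depolarizing: inconsistent with tighter "
            "binding to inactivated states (no-binding diagnostic)"
        )
    denom = (1.0 + drug_conc / kd_rest) * math.exp(abs(corrected_shift) / slope) - 1.0
    if denom <= 0.0:
        raise ValueError(
            "shift too small for measurable inactivated-state binding "
            "(no-binding diagnostic)"
        )
    return drug_conc / denom


def analyze_state_dependence(
    control: AvailabilityCurve,
    drug: AvailabilityCurve,
    resting_block: float,
    control_drift: float = 0.0,
    normalize_drug: str = "own-max",
) -> ShiftAnalysis:
    """Full chain: Boltzmann fits, drift correction, K_r and K_i inference.

    The shift equation uses the *control* fit's slope factor: the two-state
    model assumes a common slope, and the drug-curve slope estimate absorbs
    noise and secondary effects.  ``normalize_drug`` selects whether the drug
    curve is rescaled to its own maximum before fitting (default; resting
    block is carried separately) or fitted as passed (``"none"``).
    """
    if control.prepulse_v.shape != drug.prepulse_v.shape or not np.allclose(
        control.prepulse_v, drug.prepulse_v
    ):
        raise ValueError("control and drug curves must share the prepulse grid")
    if control.prepulse_duration != drug.prepulse_duration:
        raise ValueError("control and drug curves must share the prepulse duration")

    cfit = fit_boltzmann(control)
    if not cfit.converged:
        raise RuntimeError("stage control-fit: Boltzmann fit did not converge")

    if normalize_drug == "own-max":
        dcurve = AvailabilityCurve(
            drug.prepulse_v,
            drug.current_norm / max(drug.current_norm.max(), 1e-300),
            drug.prepulse_duration,
            drug.test_v,
            drug.drug_conc,
            drug.label,
        )
    elif normalize_drug == "none":
        dcurve = drug
    else:
        raise ValueError(f"unknown normalize_drug mode {normalize_drug!r}")
    dfit = fit_boltzmann(dcurve)
    if not dfit.converged:
        raise RuntimeError("stage drug-fit: Boltzmann fit did not converge")

    raw = dfit.params.v_half - cfit.params.v_half
    corrected = drift_corrected_shift(raw, control_drift)
    try:
        kr = infer_kd_rest(resting_block, drug.drug_conc)
    except ValueError as e:
        raise ValueError(f"stage kd-rest: {e}") from e
    if corrected == 0.0:
        ki = kr
    else:
        try:
            ki = infer_kd_inact(corrected, cfit.params.slope, drug.drug_conc, kr)
        except ValueError as e:
            raise ValueError(f"stage kd-inact: {e}") from e
    return ShiftAnalysis(
        control_fit=cfit,
        drug_fit=dfit,
        raw_shift=raw,
        control_drift=control_drift,
        corrected_shift=corrected,
        kd_rest=kr,
        kd_inact=ki,
    )
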