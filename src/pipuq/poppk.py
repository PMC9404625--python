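"""Two-compartment piperacillin population-PK model with parallel
linear / Michaelis-Menten elimination.

Structural model (amounts A1 central, A2 peripheral, C = A1/V in mg/L):

    dA1/dt = R(t) - (CL/V)*A1 - Vmax*C/(Km + C) - (Q/V)*A1 + (Q/Vp)*A2
    dA2/dt = (Q/V)*A1 - (Q/Vp)*A2

Both elimination pathways act on the central compartment and are driven by
the central concentration — the standard pharmacometric convention.  The
covariate model scales clearance with creatinine clearance (normalised to
100 mL/min) and allometric body weight (normalised to 70 kg, exponent 0.75
on clearances, 1 on volumes):

    CL = TVCL * (CLcr/100) * (W/70)^0.75
    V  = TVV  * (W/70)
    Vp = TVVp * (W/70)
    Q  = TVQ  * (W/70)^0.75

Km and Vmax carry no covariates.  At steady state under a constant infusion
the peripheral compartment carries no net flux, so the concentration solves
the scalar mass balance  rate = CL*C + Vmax*C/(Km + C).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.integrate import solve_ivp

__all__ = [
    "TypicalValues",
    "PKParameters",
    "DosingEvent",
    "ConcentrationSeries",
    "individual_parameters",
    "simulate",
    "steady_state_concentration",
    "a_priori_predict",
]


def _check_positive(**kwargs):
    for name, value in kwargs.items():
        if not (value > 0):
            raise ValueError(f"{name} must be > 0, got {value}")


@dataclass(frozen=True)
class TypicalValues:
    """Population-typical parameters of the published piperacillin model.

    tvcl L/h, tvv L, tvvp L, tvq L/h, km mg/L, vmax mg/h.
    """

    tvcl: float = 9.0
    tvv: float = 6.18
    tvvp: float = 11.17
    tvq: float = 15.61
    km: float = 37.09
    vmax: float = 353.57

    def __post_init__(self):
        _check_positive(
            tvcl=self.tvcl, tvv=self.tvv, tvvp=self.tvvp, tvq=self.tvq, km=self.km, vmax=self.vmax
        )


@dataclass(frozen=True)
class PKParameters:
    """Individual two-compartment parameters (CL L/h, V L, Vp L, Q L/h, Km mg/L, Vmax mg/h)."""

    cl: float
    v: float
    vp: float
    q: float
    km: float
    vmax: float

    def __post_init__(self):
        _check_positive(cl=self.cl, v=self.v, vp=self.vp, km=self.km)
        if self.q < 0 or self.vmax < 0:
            raise ValueError("q and vmax must be >= 0")


@dataclass(frozen=True)
class DosingEvent:
    """Constant-rate infusion of the piperacillin component.

    start and duration in hours since therapy start; rate in mg/h.
    Overlapping events add their rates.
    """

    start: float
    duration: float
    rate: float

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if self.rate < 0 or self.start < 0:
            raise ValueError("start and rate must be >= 0")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class ConcentrationSeries:
    """Central-compartment concentration (mg/L) at strictly increasing times (h)."""

    times: np.ndarray
    central_conc: np.ndarray


def individual_parameters(tv: TypicalValues, clcr: float, weight: float) -> PKParameters:
    """Apply the covariate model to get individual parameters.

    Parameters
    ----------
    tv : TypicalValues
    clcr : float
        Creatinine clearance (mL/min).
    weight : float
        Body weight (kg).
    """
    _check_positive(clcr=clcr, weight=weight)
    w = weight / 70.0
    return PKParameters(
        cl=tv.tvcl * (clcr / 100.0) * w**0.75,
        v=tv.tvv * w,
        vp=tv.tvvp * w,
        q=tv.tvq * w**0.75,
        km=tv.km,
        vmax=tv.vmax,
    )


def _rate_at(events: Sequence[DosingEvent], t: float) -> float:
    return sum(e.rate for e in events if e.start <= t < e.end)


def simulate(
    params: PKParameters,
    events: Sequence[DosingEvent],
    times,
    rtol: float = 1e-8,
) -> ConcentrationSeries:
    """Integrate the two-compartment ODEs under a piecewise-constant infusion.

    Starts from empty compartments at t = 0.  Integration restarts at every
    infusion-rate change so the discontinuities never cross a solver step.

    Parameters
    ----------
    params : PKParameters
    events : sequence of DosingEvent
    times : array of hours (>= 0, strictly increasing) at which to report the
        central concentration.
    rtol : relative tolerance of the stiff-capable integrator.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a nonempty 1-D array")
    if np.any(times < 0) or np.any(np.diff(times) <= 0):
        raise ValueError("times must be nonnegative and strictly increasing")

    cl, v, vp, q, km, vmax = params.cl, params.v, params.vp, params.q, params.km, params.vmax

    def rhs(t, a, rate):
        c = a[0] / v
        elim = (cl / v) * a[0] + vmax * c / (km + c)
        transfer = (q / v) * a[0] - (q / vp) * a[1]
        return [rate - elim - transfer, transfer]

    # breakpoints: all rate changes plus the final reporting time
    t_end = float(times[-1])
    cuts = sorted({0.0, t_end} | {e.start for e in events} | {e.end for e in events})
    cuts = [c for c in cuts if 0.0 <= c <= t_end]
    if cuts[-1] < t_end:
        cuts.append(t_end)

    a = np.zeros(2)
    out_t, out_c = [], []
    if times[0] == 0.0:
        out_t.append(0.0)
        out_c.append(0.0)
    for left, right in zip(cuts[:-1], cuts[1:]):
        rate = _rate_at(events, (left + right) / 2.0)
        report = times[(times > left) & (times <= right)]
        # always evaluate at the segment end so the state carries over exactly
        t_eval = np.unique(np.append(report, right))
        sol = solve_ivp(
            rhs,
            (left, right),
            a,
            method="LSODA",
            t_eval=t_eval,
            rtol=rtol,
            atol=1e-8,
            args=(rate,),
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed on [{left}, {right}]: {sol.message}")
        keep = np.isin(sol.t, report)
        out_t.extend(sol.t[keep])
        out_c.extend(sol.y[0, keep] / v)
        a = sol.y[:, -1]

    conc = np.maximum(np.asarray(out_c, dtype=float), 0.0)
    return ConcentrationSeries(times=np.asarray(out_t, dtype=float), central_conc=conc)


def steady_state_concentration(params: PKParameters, rate: float) -> float:
    """Steady-state central concentration under a constant infusion.

    Solves  rate = CL*C + Vmax*C/(Km + C)  for C >= 0.  The left side is 0 at
    C = 0 and the right side is strictly increasing in C, so the root is
    unique; it is bracketed and found by Brent's method.
    """
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    if rate == 0:
        return 0.0

    def balance(c):
        return params.cl * c + params.vmax * c / (params.km + c) - rate

    hi = rate / params.cl + params.km + 1.0
    while balance(hi) < 0:
        hi *= 2.0
    return float(optimize.brentq(balance, 0.0, hi, xtol=1e-12, rtol=1e-14))


def a_priori_predict(tv: TypicalValues, clcr: float, weight: float, rate: float) -> float:
    """Deterministic a-priori steady-state prediction from population-typical values."""
    return steady_state_concentration(individual_parameters(tv, clcr, weight), rate)
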