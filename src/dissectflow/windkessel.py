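"""Three-element Windkessel (RCR) outlet model.

The model lumps the vasculature downstream of an outlet into a
characteristic (proximal) resistance Rp in series with a parallel
compliance C and distal resistance Rd, discharging at a reference
pressure Pout:

    C dPc/dt = Q - (Pc - Pout)/Rd,      P = Pc + Q * Rp.

Parameters are held in clinical units (mmHg·min/L, L/mmHg, mmHg) and
converted to SI for integration.  Calibration replicates boundary-
condition tuning against measured flow and pressure: the total
resistance follows from the mean pressure and mean flow, the Rp/Rd
split is a fixed fraction, and the compliance is found by bisection on
the simulated pulse pressure (which is strictly decreasing in C).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .units import LMIN_TO_M3S, MMHG_TO_PA, PA_TO_MMHG, M3S_TO_LMIN
from .waveform import FlowWaveform

__all__ = [
    "WindkesselParams",
    "PressureTargets",
    "PressureWaveform",
    "simulate_rcr",
    "calibrate_rcr",
    "impedance",
]

# resistance: mmHg·min/L -> Pa·s/m^3 ; compliance: L/mmHg -> m^3/Pa
_R_TO_SI = MMHG_TO_PA / LMIN_TO_M3S
_C_TO_SI = 1e-3 / MMHG_TO_PA


@dataclass(frozen=True)
class WindkesselParams:
    """RCR parameters for one outlet, in clinical units."""

    proximal_resistance_Rp: float  # mmHg·min/L
    compliance_C: float            # L/mmHg
    distal_resistance_Rd: float    # mmHg·min/L
    distal_pressure_Pout: float = 0.0  # mmHg

    def __post_init__(self) -> None:
        if self.proximal_resistance_Rp <= 0 or self.distal_resistance_Rd <= 0:
            raise ValueError("resistances must be > 0")
        if self.compliance_C <= 0:
            raise ValueError("compliance must be > 0")
        if not self.proximal_resistance_Rp < self.distal_resistance_Rd:
            raise ValueError("arterial convention requires Rp < Rd")

    @property
    def total_resistance(self) -> float:
        return self.proximal_resistance_Rp + self.distal_resistance_Rd


@dataclass(frozen=True)
class PressureTargets:
    """Calibration targets from invasive pressure measurement."""

    mean_pressure: float   # mmHg
    pulse_pressure: float  # mmHg (systolic - diastolic)

    def __post_init__(self) -> None:
        if self.pulse_pressure < 0:
            raise ValueError("pulse pressure must be >= 0")


@dataclass(frozen=True)
class PressureWaveform:
    """One periodic cycle of outlet pressure (mmHg)."""

    time_s: np.ndarray
    pressure_mmHg: np.ndarray
    period_s: float
    cycles_run: int = 0

    def cycle_mean(self) -> float:
        t = np.append(self.time_s, self.time_s[0] + self.period_s)
        p = np.append(self.pressure_mmHg, self.pressure_mmHg[0])
        return float(np.trapezoid(p, t) / self.period_s)

    def pulse(self) -> float:
        return float(self.pressure_mmHg.max() - self.pressure_mmHg.min())


def _periodic_interp(times: np.ndarray, waveform: FlowWaveform) -> np.ndarray:
    """Linear periodic interpolation of the waveform at given times."""
    t_ext = np.append(waveform.time_s, waveform.time_s[0] + waveform.period_s)
    q_ext = np.append(waveform.flow_L_min, waveform.flow_L_min[0])
    return np.interp(np.mod(times, waveform.period_s), t_ext, q_ext)


def simulate_rcr(params: WindkesselParams, inflow: FlowWaveform,
                 cycles: int = 100, dt: float | None = None,
                 periodicity_tol: float = 1e-3) -> PressureWaveform:
    """Outlet-face pressure under a prescribed periodic inflow.

    Integrates the compliance state with implicit Euler and returns the
    final cycle once the cycle-mean pressure changes by less than
    ``periodicity_tol`` (relative) between cycles.  Raises if the
    solution has not become periodic within ``cycles`` cycles.
    """
    sample_dt = float(np.min(np.diff(inflow.time_s)))
    if dt is None:
        dt = min(sample_dt, inflow.period_s / 200.0)
    if dt > sample_dt + 1e-12:
        raise ValueError("dt must not exceed the inflow sampling interval")
    if cycles < 1:
        raise ValueError("cycles must be >= 1")

    n = max(int(round(inflow.period_s / dt)), 4)
    dt = inflow.period_s / n
    t_cycle = dt * np.arange(n + 1)
    q_lmin = _periodic_interp(t_cycle, inflow)
    q_si = q_lmin * LMIN_TO_M3S

    rp = params.proximal_resistance_Rp * _R_TO_SI
    rd = params.distal_resistance_Rd * _R_TO_SI
    c = params.compliance_C * _C_TO_SI
    pout = params.distal_pressure_Pout * MMHG_TO_PA

    q_mean = inflow.cycle_mean() * LMIN_TO_M3S
    a = 1.0 + dt / (rd * c)

    # The implicit-Euler map over one cycle is affine in the compliance
    # state, pc_end = pc_start / a**n + B: start at its fixed point so
    # the returned cycle is periodic from the outset.
    pc = 0.0
    for k in range(1, n + 1):
        pc = (pc + dt * (q_si[k] / c + pout / (rd * c))) / a
    a_tot = a ** (-float(n))
    pc = pc / (1.0 - a_tot) if a_tot < 1.0 else pout + q_mean * rd

    prev_mean = None
    for cyc in range(cycles):
        p_hist = np.empty(n + 1)
        p_hist[0] = (pc + q_si[0] * rp) * PA_TO_MMHG
        for k in range(1, n + 1):
            pc = (pc + dt * (q_si[k] / c + pout / (rd * c))) / a
            p_hist[k] = (pc + q_si[k] * rp) * PA_TO_MMHG
        mean = float(np.trapezoid(p_hist, t_cycle) / inflow.period_s)
        if prev_mean is not None:
            denom = max(abs(mean), 1e-9)
            if abs(mean - prev_mean) / denom < periodicity_tol:
                return PressureWaveform(t_cycle[:-1], p_hist[:-1],
                                        inflow.period_s, cycles_run=cyc + 1)
        prev_mean = mean
    raise RuntimeError(
        f"RCR simulation did not reach a periodic solution in {cycles} "
        f"cycles (last cycle means {prev_mean:.4f} / {mean:.4f} mmHg)")


def impedance(params: WindkesselParams, omega_rad_s) -> np.ndarray:
    """Complex input impedance Z(w) = Rp + Rd/(1 + j w Rd C), mmHg·min/L.

    ``omega_rad_s`` is the angular frequency in rad/s; the RdC product
    is converted from minutes to seconds internally.
    """
    w = np.asarray(omega_rad_s, dtype=float)
    tau_s = params.distal_resistance_Rd * params.compliance_C * 60.0
    return params.proximal_resistance_Rp + \
        params.distal_resistance_Rd / (1.0 + 1j * w * tau_s)


def calibrate_rcr(inflow: FlowWaveform, targets: PressureTargets,
                  rp_fraction: float = 0.1, pout_mmHg: float = 0.0,
                  pulse_tol_mmHg: float = 0.05, dt: float | None = None,
                  ) -> WindkesselParams:
    """Fit RCR parameters to a measured inflow and pressure targets.

    R_total = (mean - Pout) / mean flow; Rp is ``rp_fraction`` of the
    total; C is found by bisection on the simulated pulse pressure.
    Raises if the target pulse pressure is outside the range achievable
    for the given resistance split.
    """
    q_mean = inflow.cycle_mean()
    if q_mean <= 0:
        raise ValueError("cycle-mean inflow must be > 0 for calibration")
    if not (0 < rp_fraction < 1):
        raise ValueError("rp_fraction must be in (0, 1)")
    r_total = (targets.mean_pressure - pout_mmHg) / q_mean
    if r_total <= 0:
        raise ValueError("mean pressure target must exceed Pout")
    rp = rp_fraction * r_total
    rd = r_total - rp

    def pulse_of(c: float) -> float:
        p = WindkesselParams(rp, c, rd, pout_mmHg)
        return simulate_rcr(p, inflow, dt=dt,
                            periodicity_tol=1e-4).pulse()

    log_lo, log_hi = np.log(1e-6), np.log(10.0)
    pulse_hi = pulse_of(np.exp(log_lo))  # small C -> large pulse
    pulse_lo = pulse_of(np.exp(log_hi))  # large C -> small pulse
    if not (pulse_lo <= targets.pulse_pressure <= pulse_hi):
        raise ValueError(
            f"target pulse pressure {targets.pulse_pressure} mmHg is outside "
            f"the achievable range [{pulse_lo:.3f}, {pulse_hi:.3f}] mmHg for "
            f"this resistance split")

    log_c = brentq(lambda lc: pulse_of(np.exp(lc)) - targets.pulse_pressure,
                   log_lo, log_hi, xtol=1e-6)
    c = float(np.exp(log_c))
    params = WindkesselParams(rp, c, rd, pout_mmHg)
    achieved = simulate_rcr(params, inflow, dt=dt, periodicity_tol=1e-4)
    if abs(achieved.pulse() - targets.pulse_pressure) > pulse_tol_mmHg * 10:
        raise RuntimeError("pulse-pressure bisection failed to converge")
    return params
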