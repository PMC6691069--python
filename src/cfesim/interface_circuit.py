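"""Time-domain simulation of the electrode-tissue interface circuit.

Topology (single-interface, symmetric-electrode assumption)::

    V_in --+--[ RC ladder (n branches) || Faradaic diode-memristor pair ]--+
           |                                                              |
         (source)                                                  post-interface
           |                                                              |
           0 --------------[ R_tissue ]---- V_out ----[ R_s ]-------------+

i.e. the source drives the interface element, then the spreading resistance
R_s, then the tissue load R_tissue to ground.  Two output nodes are exposed:

* ``after_interface`` - directly downstream of the interface element,
  V = I * (R_s + R_tissue);
* ``tissue`` (default) - the node feeding the tissue load, V = I * R_tissue.
  This is the waveform handed to the finite-element model as the electrode
  boundary potential: the stimulus actually delivered, past both the
  double-layer and the spreading resistance.

The Faradaic pair is phenomenological: each polarity is a diode in series
with a memristor whose resistance decreases with delivered charge,

    V_if = sign * [ n V_T ln(1 + I/I_s) + M(q) I ],
    M(q) = max(M_min, M_0 / (1 + |q|/q_0)).

Default Faradaic parameters are a calibration: they are chosen so that a
20 V / 50 ms pulse into tissue loads of 522 and 174 Ohm (the in-silico
tandem and alternate tissue resistances) delivers end-of-plateau electrode
potentials of about 12 and 7 V.  See docs/methods.md.

States are the branch capacitor voltages and the Faradaic charge; each step
solves the algebraic node equation for the interface voltage by safeguarded
Newton and advances the states with the trapezoidal rule (A-stable, second
order, fixed step => bit-reproducible).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import ValidationError, SolverError

__all__ = [
    "FaradaicParams", "PulseSpec", "CircuitResponse",
    "make_pulse_train", "faradaic_current", "simulate_interface",
    "relative_loss", "DEFAULT_FARADAIC",
]


@dataclass
class FaradaicParams:
    """Diode-memristor branch parameters (anti-parallel pair).

    I_s        : A, diode saturation current
    n_ideality : dimensionless diode ideality factor
    V_T        : V, thermal voltage
    M_0        : Ohm, memristance at zero delivered charge
    q_0        : C, charge scale of the memristance decay
    M_min      : Ohm, memristance floor
    """

    I_s: float = 1e-6
    n_ideality: float = 2.0
    V_T: float = 0.02585
    M_0: float = 50.0
    q_0: float = 1e-3
    M_min: float = 10.0
    enabled: bool = True

    def __post_init__(self):
        for name in ("I_s", "n_ideality", "V_T", "M_0", "q_0", "M_min"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"FaradaicParams.{name} must be > 0")
        if self.M_min > self.M_0:
            raise ValidationError("M_min must be <= M_0")

    def memristance(self, q: float) -> float:
        return max(self.M_min, self.M_0 / (1.0 + abs(q) / self.q_0))


#: default calibrated Faradaic branch (see module docstring)
DEFAULT_FARADAIC = FaradaicParams()


@dataclass
class PulseSpec:
    """Trapezoidal constant-voltage pulse train.

    One pulse: linear rise over `rise_time`, plateau until `width` after
    onset, linear fall over `fall_time`.  Pulses repeat every
    width + fall_time + inter_pulse_gap.
    """

    amplitude: float = 20.0
    width: float = 50e-3
    rise_time: float = 10e-6
    fall_time: float = 10e-6
    n_pulses: int = 1
    inter_pulse_gap: float = 50e-3

    def __post_init__(self):
        if min(self.width, self.rise_time, self.fall_time) < 0 or self.inter_pulse_gap < 0:
            raise ValidationError("pulse times must be non-negative")
        if self.width - self.rise_time < 0:
            raise ValidationError("plateau would be negative: width < rise_time")
        if self.n_pulses < 1:
            raise ValidationError("n_pulses must be >= 1")

    @property
    def period(self) -> float:
        return self.width + self.fall_time + self.inter_pulse_gap

    @property
    def total_duration(self) -> float:
        """Time from first onset to the end of the last fall ramp."""
        return (self.n_pulses - 1) * self.period + self.width + self.fall_time

    def breakpoints(self) -> np.ndarray:
        """Corner times of the trapezoids (integration grid anchors)."""
        pts = [0.0]
        for k in range(self.n_pulses):
            t0 = k * self.period
            pts += [t0, t0 + self.rise_time, t0 + self.width,
                    t0 + self.width + self.fall_time]
        return np.unique(np.asarray(pts))

    def value(self, t):
        """Source voltage at time(s) t (vectorized)."""
        t = np.asarray(t, dtype=float)
        tau = np.mod(t, self.period)
        # last pulse has no following period wrap; mod handles repeats uniformly
        in_train = (t >= 0) & (t <= self.total_duration + 1e-18)
        rise = np.clip(tau / self.rise_time, 0.0, 1.0) if self.rise_time > 0 \
            else np.ones_like(tau)
        fall = np.where(tau <= self.width, 1.0,
                        np.clip(1.0 - (tau - self.width) / self.fall_time, 0.0, 1.0)
                        if self.fall_time > 0 else 0.0)
        v = self.amplitude * np.minimum(rise, fall) * in_train
        return float(v) if v.ndim == 0 else v


def make_pulse_train(spec: PulseSpec) -> Callable[[np.ndarray], np.ndarray]:
    """Waveform function of time for the pulse train."""
    return spec.value


def _branch_current(v_abs: float, M: float, p: FaradaicParams) -> float:
    """Solve a ln(1 + I/I_s) + M I = v_abs for I >= 0 (one conducting branch).

    Monotone scalar equation; Newton with bisection safeguard on [0, v/M].
    """
    if v_abs <= 0.0:
        return 0.0
    a = p.n_ideality * p.V_T
    lo, hi = 0.0, v_abs / M
    i = v_abs / (M + a / p.I_s)  # exact in the sub-threshold limit
    for _ in range(60):
        g = a * np.log1p(i / p.I_s) + M * i - v_abs
        if g > 0:
            hi = i
        else:
            lo = i
        dg = a / (p.I_s + i) + M
        step = g / dg
        i_new = i - step
        if not (lo < i_new < hi):
            i_new = 0.5 * (lo + hi)
        if abs(i_new - i) <= 1e-14 * (1.0 + abs(i)):
            return i_new
        i = i_new
    return i


def faradaic_current(V_if: float, q: float, params: FaradaicParams,
                     with_derivative: bool = False):
    """Signed Faradaic current of the anti-parallel diode-memristor pair.

    Odd in V_if at fixed q; defined for all real V_if.  With
    ``with_derivative=True`` also returns dI/dV_if.
    """
    if not params.enabled:
        return (0.0, 0.0) if with_derivative else 0.0
    M = params.memristance(q)
    i = _branch_current(abs(V_if), M, params)
    cur = float(np.sign(V_if)) * i
    if not with_derivative:
        return cur
    a = params.n_ideality * params.V_T
    didv = (params.I_s + i) / (a + M * (params.I_s + i))
    return cur, didv


@dataclass
class CircuitResponse:
    """Sampled interface-circuit trajectory.

    v_out follows the configured read point (`read_point` attribute);
    `v_after_interface` and `v_tissue` are always available.
    """

    time: np.ndarray                 # s, strictly increasing
    v_in: np.ndarray                 # V, source
    v_interface: np.ndarray          # V, drop across the interface element
    v_after_interface: np.ndarray    # V = I (R_s + R_tissue)
    v_tissue: np.ndarray             # V = I R_tissue (electrode boundary potential)
    i_total: np.ndarray              # A
    q: np.ndarray                    # C, Faradaic charge
    branch_voltages: np.ndarray      # V, (n_samples, n_branches) capacitor voltages
    read_point: str = "tissue"
    pulse: PulseSpec | None = None

    @property
    def v_out(self) -> np.ndarray:
        return self.v_tissue if self.read_point == "tissue" else self.v_after_interface

    def at(self, t: float) -> dict:
        """Linear interpolation of the scalar channels at time t."""
        out = {}
        for name in ("v_in", "v_interface", "v_after_interface", "v_tissue",
                     "i_total", "q"):
            out[name] = float(np.interp(t, self.time, getattr(self, name)))
        out["v_out"] = float(np.interp(t, self.time, self.v_out))
        return out

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({
            "time_s": self.time,
            "v_out_V": self.v_out,
            "i_total_A": self.i_total,
            "q_C": self.q,
        }).to_csv(path, index=False, float_format="%.12g")


def _time_grid(breakpoints: np.ndarray, t_end: float, dt_max: float) -> np.ndarray:
    """Uniform-per-segment grid hitting every breakpoint exactly."""
    pts = np.unique(np.clip(np.append(breakpoints, [0.0, t_end]), 0.0, t_end))
    segs = [np.array([0.0])]
    for a, b in zip(pts[:-1], pts[1:]):
        if b - a <= 1e-18:
            continue
        n = max(1, int(np.ceil((b - a) / dt_max - 1e-12)))
        segs.append(np.linspace(a, b, n + 1)[1:])
    return np.concatenate(segs)


def simulate_interface(network,
                       R_s: float,
                       faradaic: FaradaicParams | None,
                       R_tissue: float,
                       pulse: PulseSpec | None = None,
                       dt_max: float = 1e-6,
                       *,
                       drive: Callable | None = None,
                       t_end: float | None = None,
                       extra_breakpoints=(),
                       initial_branch_voltages: np.ndarray | None = None,
                       initial_charge: float = 0.0,
                       reset_charge_between_pulses: bool = False,
                       read_point: str = "tissue",
                       store_every: int = 1) -> CircuitResponse:
    """Integrate the interface circuit driven by a pulse train (or custom drive).

    network : RCNetwork (any object with arrays .R and .C)
    faradaic: FaradaicParams or None (None = non-Faradaic interface)
    drive   : optional waveform function of time overriding `pulse`
    dt_max  : s, fixed integration step (trapezoidal rule); grid lands exactly
              on the pulse corner times.

    States start at zero (capacitors discharged, no delivered charge) unless
    warm-started via `initial_branch_voltages` / `initial_charge`.
    """
    if R_tissue <= 0:
        raise ValidationError("R_tissue must be > 0")
    if dt_max <= 0:
        raise ValidationError("dt_max must be > 0")
    if read_point not in ("tissue", "after_interface"):
        raise ValidationError(f"unknown read point {read_point!r}")
    Rb = np.asarray(network.R, dtype=float)
    Cb = np.asarray(network.C, dtype=float)
    if Rb.size == 0:
        raise ValidationError("empty network")

    if drive is None:
        if pulse is None:
            raise ValidationError("either pulse or drive must be given")
        drive = make_pulse_train(pulse)
        bps = pulse.breakpoints()
        if t_end is None:
            t_end = pulse.total_duration + 2e-3
    else:
        bps = np.asarray([0.0])
        if t_end is None:
            raise ValidationError("t_end required with a custom drive")
    if len(extra_breakpoints):
        bps = np.union1d(bps, np.asarray(extra_breakpoints, dtype=float))

    tgrid = _time_grid(bps, t_end, dt_max)
    nt = tgrid.size
    R_tot = R_s + R_tissue

    v = np.zeros(Rb.size) if initial_branch_voltages is None \
        else np.array(initial_branch_voltages, dtype=float)
    q = float(initial_charge)
    fa = faradaic if (faradaic is not None and faradaic.enabled) else None

    pulse_onsets = set()
    if reset_charge_between_pulses and pulse is not None:
        pulse_onsets = {round(k * pulse.period, 12) for k in range(1, pulse.n_pulses)}

    vin_all = np.asarray(drive(tgrid), dtype=float)

    n_keep = (nt - 1) // store_every + 1
    out_t = np.empty(n_keep)
    out = {k: np.empty(n_keep) for k in
           ("v_in", "v_if", "i", "q")}
    out_branch = np.empty((n_keep, Rb.size))

    def solve_vif(vin, b, G, q_now, v_guess):
        """Newton with bisection safeguard on the (monotone) node equation."""
        if fa is None:
            return (vin + R_tot * b) / (1.0 + R_tot * G)
        x = v_guess
        lo, hi = None, None
        for _ in range(80):
            i_f, di_f = faradaic_current(x, q_now, fa, with_derivative=True)
            F = x * (1.0 + R_tot * G) - R_tot * b + R_tot * i_f - vin
            if abs(F) <= 1e-12 * (1.0 + abs(vin)):
                return x
            if F > 0:
                hi = x
            else:
                lo = x
            dF = 1.0 + R_tot * (G + di_f)
            x_new = x - F / dF
            if lo is not None and hi is not None and not (lo < x_new < hi):
                x_new = 0.5 * (lo + hi)
            elif lo is None and x_new > x:  # keep stepping toward the bracket
                x_new = min(x_new, x + max(1.0, abs(vin)))
            elif hi is None and x_new < x:
                x_new = max(x_new, x - max(1.0, abs(vin)))
            if abs(x_new - x) <= 1e-14 * (1.0 + abs(x)):
                return x_new
            x = x_new
        raise SolverError("interface Newton did not converge",
                          state={"t_v_in": vin, "q": q_now, "v_if": x})

    # initial algebraic solve: instantaneous network conductance (capacitors hold v)
    G0 = np.sum(1.0 / Rb)
    b0 = np.sum(v / Rb)
    v_if = solve_vif(vin_all[0], b0, G0, q, vin_all[0] * 0.5)
    i_f0 = faradaic_current(v_if, q, fa) if fa is not None else 0.0
    i_tot = np.sum((v_if - v) / Rb) + i_f0

    ptr = 0
    out_t[ptr] = tgrid[0]
    out["v_in"][ptr] = vin_all[0]
    out["v_if"][ptr] = v_if
    out["i"][ptr] = i_tot
    out["q"][ptr] = q
    out_branch[ptr] = v
    ptr += 1

    dt_prev = -1.0
    hn = an = None
    for k in range(1, nt):
        dt = tgrid[k] - tgrid[k - 1]
        if abs(dt - dt_prev) > 1e-15 * dt:
            hn = dt / (2.0 * Rb * Cb)
            an = 1.0 / (Rb * (1.0 + hn))
            G = float(np.sum(an))
            dt_prev = dt
        if pulse_onsets and round(tgrid[k - 1], 12) in pulse_onsets:
            q = 0.0
        b = float(np.sum(an * (v * (1.0 - hn) + hn * v_if)))
        i_f_old = faradaic_current(v_if, q, fa) if fa is not None else 0.0
        v_if_new = solve_vif(vin_all[k], b, G, q, v_if)
        v = (v * (1.0 - hn) + hn * (v_if + v_if_new)) / (1.0 + hn)
        if fa is not None:
            i_f_new = faradaic_current(v_if_new, q, fa)
            q += 0.5 * dt * (i_f_old + i_f_new)
        else:
            i_f_new = 0.0
        v_if = v_if_new
        i_tot = float(np.sum((v_if - v) / Rb)) + i_f_new
        if k % store_every == 0 or k == nt - 1:
            if ptr >= n_keep:  # tail sample when nt-1 not on the stride
                for key in out:
                    out[key] = np.append(out[key], 0.0)
                out_t = np.append(out_t, 0.0)
                out_branch = np.vstack([out_branch, v])
            out_t[ptr] = tgrid[k]
            out["v_in"][ptr] = vin_all[k]
            out["v_if"][ptr] = v_if
            out["i"][ptr] = i_tot
            out["q"][ptr] = q
            out_branch[ptr] = v
            ptr += 1

    out_t = out_t[:ptr]
    i_arr = out["i"][:ptr]
    return CircuitResponse(
        time=out_t,
        v_in=out["v_in"][:ptr],
        v_interface=out["v_if"][:ptr],
        v_after_interface=i_arr * R_tot,
        v_tissue=i_arr * R_tissue,
        i_total=i_arr,
        q=out["q"][:ptr],
        branch_voltages=out_branch[:ptr],
        read_point=read_point,
        pulse=pulse,
    )


def relative_loss(response: CircuitResponse, applied: float) -> tuple[float, float]:
    """(peak_loss, steady_loss) of the delivered potential relative to `applied`.

    peak_loss   = 1 - max(v_out) / applied over the rise and first half of the
                  pulse; steady_loss = 1 - v_out(end of plateau) / applied.
    Requires the response to cover at least one full pulse.
    """
    if applied <= 0:
        raise ValidationError("applied voltage must be > 0")
    if response.pulse is None:
        raise ValidationError("response carries no pulse specification")
    p = response.pulse
    t = response.time
    if t[-1] < p.width:
        raise ValidationError("response does not cover a full pulse")
    early = (t >= 0) & (t <= 0.5 * p.width)
    peak = float(np.max(response.v_out[early]))
    steady = float(np.interp(p.width, t, response.v_out))
    return 1.0 - peak / applied, 1.0 - steady / applied
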