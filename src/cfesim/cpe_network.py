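"""Synthesis of a constant phase element as a finite ladder of series-RC branches.

A CPE with exponent m can be approximated by n parallel branches, each a
resistor R_n in series with a capacitor C_n, in geometric progression.  The
branch-density parameter k is the ratio of successive CAPACITANCES; for the
ladder admittance to scale as (j w)^m the progression must then be

    C_n = C_mid * k^(n - center)
    R_n = R_mid * k^(m/(1-m) * (n - center))
    tau_n = R_n C_n = tau_mid * K^(n - center),   K = k^(1/(1-m))

with the middle branch at the band centre, tau_mid = 1/(2 pi sqrt(f_lo f_hi)).
The constant-phase plateau requires the tau progression to extend well beyond
the measurement band: the capacitive edge of a truncated ladder relaxes
toward 90 degrees over ~1/((1-m) ln K) branches, so a 61-branch, k = 1.18
ladder (K ~ 1.83, ~15.7 decades of tau) holds the phase flat at m*90 across
the 0.1 Hz - 10 kHz window, whereas reading k as the tau ratio directly
(4.3 decades) leaves no plateau at all.  Smaller k at fixed band = more
branches per decade = smaller phase ripple.

The absolute scale (R_mid, C_mid) is fixed by a magnitude calibration: the
ladder impedance magnitude at a reference frequency is pinned to a target
value; (theta, k, n) do not determine it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .eis import theta_to_m
from .interface_circuit import FaradaicParams, PulseSpec  # re-exported topology partners

__all__ = [
    "CPEInterfaceParams", "RCNetwork", "synthesize_network",
    "network_impedance", "export_spice_netlist", "parse_spice_netlist",
    "write_network_csv",
]


@dataclass
class CPEInterfaceParams:
    """Electrode-interface CPE parameters.

    Defaults are the optimized values for the 8-channel platinum cochlear
    array: theta_CPE = 65.3 deg, k = 1.18, 61 branches, R_s = 297 Ohm,
    spanning the 0.1 Hz - 10 kHz EIS band.  The absolute impedance scale is
    not determined by (theta, k, n); it is pinned by `calibration_target_ohm`
    at `calibration_frequency_hz` (default 100 kOhm at 0.1 Hz, an
    order-of-magnitude match to measured low-frequency magnitudes).
    """

    theta_cpe_deg: float = 65.3
    k: float = 1.18
    n_branches: int = 61
    R_s: float = 297.0
    f_lo: float = 0.1
    f_hi: float = 10e3
    calibration_frequency_hz: float = 0.1
    calibration_target_ohm: float = 100e3

    def __post_init__(self):
        if not (0.0 < self.theta_cpe_deg < 90.0):
            raise ValidationError(f"theta_CPE must be in (0, 90), got {self.theta_cpe_deg}")
        if self.k <= 1.0:
            raise ValidationError(f"branch time-constant ratio k must be > 1, got {self.k}")
        if self.n_branches < 1 or self.n_branches % 2 == 0:
            raise ValidationError(f"n_branches must be odd and >= 1, got {self.n_branches}")
        if self.R_s < 0:
            raise ValidationError(f"R_s must be >= 0, got {self.R_s}")
        if not (0 < self.f_lo < self.f_hi):
            raise ValidationError("need 0 < f_lo < f_hi")
        if self.calibration_frequency_hz <= 0 or self.calibration_target_ohm <= 0:
            raise ValidationError("calibration frequency and target must be > 0")

    @property
    def m(self) -> float:
        return theta_to_m(self.theta_cpe_deg)


@dataclass
class RCNetwork:
    """Synthesized ladder: parallel branches of series (R_n, C_n)."""

    R: np.ndarray          # Ohm, per branch
    C: np.ndarray          # F, per branch
    center: int            # index of the mid-band branch
    f_lo: float
    f_hi: float

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        if self.R.size == 0 or self.R.size != self.C.size:
            raise ValidationError("R and C must be non-empty arrays of equal length")
        if np.any(self.R <= 0) or np.any(self.C <= 0):
            raise ValidationError("all R_n and C_n must be > 0")

    def __len__(self) -> int:
        return self.R.size

    @property
    def tau(self) -> np.ndarray:
        return self.R * self.C


def synthesize_network(params: CPEInterfaceParams) -> RCNetwork:
    """Build the RC ladder realizing the CPE of `params` over [f_lo, f_hi]."""
    m = params.m
    n = params.n_branches
    center = n // 2
    tau_mid = 1.0 / (2.0 * np.pi * np.sqrt(params.f_lo * params.f_hi))
    idx = np.arange(n) - center
    # unit-scale ladder (C ratio k, R ratio k^(m/(1-m))), then calibrate magnitude
    R = params.k ** (m / (1.0 - m) * idx)
    C = tau_mid * params.k ** idx
    net = RCNetwork(R=R, C=C, center=center, f_lo=params.f_lo, f_hi=params.f_hi)
    z0 = network_impedance(net, 0.0, params.calibration_frequency_hz)
    s = params.calibration_target_ohm / abs(z0)
    return RCNetwork(R=R * s, C=C / s, center=center,
                     f_lo=params.f_lo, f_hi=params.f_hi)


def network_impedance(network: RCNetwork, R_s: float, f) -> np.ndarray | complex:
    """Z(f) = R_s + [sum_n (R_n + 1/(j w C_n))^-1]^-1, exact complex arithmetic."""
    if len(network) == 0:
        raise ValidationError("empty network")
    f_arr = np.atleast_1d(np.asarray(f, dtype=float))
    if np.any(f_arr <= 0):
        raise ValidationError("frequency must be > 0")
    w = 2.0 * np.pi * f_arr[:, None]
    zb = network.R[None, :] + 1.0 / (1j * w * network.C[None, :])
    z = R_s + 1.0 / np.sum(1.0 / zb, axis=1)
    if np.isscalar(f):
        return complex(z[0])
    return z


def write_network_csv(path, network: RCNetwork) -> None:
    """Dump branch values as CSV (branch_index, R_ohm, C_farad)."""
    import pandas as pd
    pd.DataFrame({
        "branch_index": np.arange(len(network)),
        "R_ohm": network.R,
        "C_farad": network.C,
    }).to_csv(path, index=False, float_format="%.15g")


# ---------------------------------------------------------------------------
# SPICE export
# ---------------------------------------------------------------------------
# Node plan (generic SPICE3 dialect):
#   1  : source / interface top         (V_in)
#   2  : interface bottom = R_s top     (post-interface node)
#   3  : R_s bottom = tissue top        (electrode node, V_out)
#   0  : ground
#   b<i>: internal node of branch i between R<i> and C<i>
# Branch i: Rb<i> 1 b<i> <R>   /  Cb<i> b<i> 2 <C>
# Faradaic pair (optional): behavioral current sources between 1 and 2.

def export_spice_netlist(network: RCNetwork,
                         R_s: float,
                         R_tissue: float,
                         pulse: PulseSpec,
                         faradaic: FaradaicParams | None = None) -> str:
    """Emit a SPICE netlist of the full interface + tissue-load circuit."""
    if R_tissue <= 0:
        raise ValidationError("R_tissue must be > 0")
    lines = [
        "* cfesim electrode-tissue interface circuit",
        f"* {len(network)} RC branches, R_s={R_s:.6g} ohm, R_tissue={R_tissue:.6g} ohm",
        "V1 1 0 PULSE(0 {amp:.9g} 0 {tr:.9g} {tf:.9g} {pw:.9g} {per:.9g})".format(
            amp=pulse.amplitude, tr=pulse.rise_time, tf=pulse.fall_time,
            pw=max(pulse.width - pulse.rise_time, 0.0),
            per=pulse.period),
        f"RS 2 3 {R_s:.15g}",
        f"RT 3 0 {R_tissue:.15g}",
    ]
    for i, (r, c) in enumerate(zip(network.R, network.C), start=1):
        lines.append(f"RB{i} 1 B{i} {r:.15g}")
        lines.append(f"CB{i} B{i} 2 {c:.15g}")
    if faradaic is not None and faradaic.enabled:
        # behavioral anti-parallel diode-memristor pair; memristance frozen at M_0
        a = faradaic.n_ideality * faradaic.V_T
        lines.append(f"* faradaic pair: Is={faradaic.I_s:.6g} A, n*V_T={a:.6g} V, "
                     f"M0={faradaic.M_0:.6g} ohm (charge dependence not exportable)")
        lines.append(f"BF1 1 2 I=({faradaic.I_s:.9g})*(exp(max(V(1,2),0)/"
                     f"({a:.9g}+{faradaic.M_0:.9g}*{faradaic.I_s:.9g}))-1)")
        lines.append(f"BF2 2 1 I=({faradaic.I_s:.9g})*(exp(max(V(2,1),0)/"
                     f"({a:.9g}+{faradaic.M_0:.9g}*{faradaic.I_s:.9g}))-1)")
    lines.append(".tran 1u {t_end:.9g}".format(t_end=pulse.total_duration + 0.01))
    lines.append(".end")
    return "\n".join(lines) + "\n"


def parse_spice_netlist(text: str) -> dict:
    """Parse a netlist produced by :func:`export_spice_netlist`.

    Returns dict with keys R (array), C (array), R_s, R_tissue, pulse_amplitude.
    Used for round-trip verification against external circuit simulators.
    """
    rb, cb = {}, {}
    out = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("*") or line.startswith("."):
            continue
        tok = line.split()
        name = tok[0].upper()
        if name.startswith("RB"):
            rb[int(name[2:])] = float(tok[3])
        elif name.startswith("CB"):
            cb[int(name[2:])] = float(tok[3])
        elif name == "RS":
            out["R_s"] = float(tok[3])
        elif name == "RT":
            out["R_tissue"] = float(tok[3])
        elif name == "V1":
            inner = line[line.index("(") + 1:line.rindex(")")]
            out["pulse_amplitude"] = float(inner.split()[1])
    idx = sorted(rb)
    if idx != sorted(cb) or not idx:
        raise ValidationError("netlist branch R/C elements do not pair up")
    out["R"] = np.array([rb[i] for i in idx])
    out["C"] = np.array([cb[i] for i in idx])
    return out
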