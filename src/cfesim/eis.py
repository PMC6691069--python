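"""Electrochemical impedance spectroscopy (EIS) data model, generation and fitting.

An electrode in electrolyte behaves as a constant phase element (CPE) in
series with a spreading resistance R_s:

    Z(f) = R_s + K / (j 2 pi f)^m

with fractional exponent m in (0, 1).  The CPE term alone has a frequency
independent phase of m * 90 degrees (capacitive); the measured phase peak
theta therefore fixes m = theta_deg / 90.  Spectra are stored with the
capacitive phase as POSITIVE degrees in [0, 90]; the sign is flipped to the
electrical convention only inside complex arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import FormatError, ValidationError, FitError

#: canonical CSV column names
CSV_COLUMNS = ("frequency_hz", "magnitude_ohm", "phase_deg", "electrode_id")

_M_LO, _M_HI = 1e-3, 1.0 - 1e-6


@dataclass
class ImpedanceSpectrum:
    """One electrode's impedance spectrum.

    frequencies : Hz, strictly ascending, > 0
    magnitudes  : Ohm, > 0
    phases      : degrees, capacitive phase positive, in [0, 90]
    """

    frequencies: np.ndarray
    magnitudes: np.ndarray
    phases: np.ndarray
    electrode_id: str = "electrode"
    replicate: str | None = None

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        self.phases = np.asarray(self.phases, dtype=float)
        n = self.frequencies.size
        if self.magnitudes.size != n or self.phases.size != n:
            raise ValidationError(
                f"spectrum '{self.electrode_id}': arrays have unequal lengths "
                f"({n}, {self.magnitudes.size}, {self.phases.size})")
        if n == 0:
            raise ValidationError(f"spectrum '{self.electrode_id}': empty")
        bad = np.flatnonzero(self.frequencies <= 0)
        if bad.size:
            raise ValidationError(
                f"spectrum '{self.electrode_id}': non-positive frequency at row {bad[0]}")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValidationError(
                f"spectrum '{self.electrode_id}': frequencies must be strictly ascending")
        bad = np.flatnonzero(self.magnitudes <= 0)
        if bad.size:
            raise ValidationError(
                f"spectrum '{self.electrode_id}': non-positive magnitude at row {bad[0]}")
        if np.any((self.phases < 0) | (self.phases > 90)):
            raise ValidationError(
                f"spectrum '{self.electrode_id}': phases must lie in [0, 90] degrees")

    def __len__(self) -> int:
        return self.frequencies.size

    @property
    def complex_impedance(self) -> np.ndarray:
        """Complex Z with the electrical sign convention (capacitive phase negative)."""
        return self.magnitudes * np.exp(-1j * np.deg2rad(self.phases))

    def decades(self) -> float:
        return float(np.log10(self.frequencies[-1] / self.frequencies[0]))


@dataclass
class IdealCPEParams:
    """Ideal CPE + spreading resistance: Z = R_s + K/(j w)^m.

    m   : dimensionless exponent, 0 < m < 1
    K   : Ohm * (rad/s)^m magnitude coefficient
    R_s : Ohm, series (spreading) resistance
    """

    m: float
    K: float
    R_s: float = 0.0

    def __post_init__(self):
        if not (0.0 < self.m < 1.0):
            raise ValidationError(f"m must be in (0, 1), got {self.m}")
        if self.K <= 0:
            raise ValidationError(f"K must be > 0, got {self.K}")
        if self.R_s < 0:
            raise ValidationError(f"R_s must be >= 0, got {self.R_s}")

    def to_toml(self) -> str:
        """Flat key-value TOML block (CPEInterfaceParams-compatible field names)."""
        lines = [
            f"theta_cpe_deg = {self.m * 90.0!r}",
            f"m = {self.m!r}",
            f"cpe_coefficient_ohm = {self.K!r}",
            f"r_s_ohm = {self.R_s!r}",
        ]
        return "\n".join(lines) + "\n"


def theta_to_m(theta_cpe_deg: float) -> float:
    """Convert the CPE phase angle (degrees) to the fractional exponent m.

    m = 2*theta/pi with theta in radians, i.e. theta_deg / 90.
    """
    if not (0.0 < theta_cpe_deg < 90.0):
        raise ValidationError(
            f"theta_CPE must be in (0, 90) degrees, got {theta_cpe_deg}")
    return theta_cpe_deg / 90.0


def ideal_cpe_impedance(params: IdealCPEParams, f) -> np.ndarray | complex:
    """Complex impedance Z(f) = R_s + K/(j*2*pi*f)^m for f in Hz (> 0)."""
    f_arr = np.asarray(f, dtype=float)
    if np.any(f_arr <= 0):
        raise ValidationError("frequency must be > 0")
    w = 2.0 * np.pi * f_arr
    z = params.R_s + params.K * w ** (-params.m) * np.exp(-1j * np.pi / 2.0 * params.m)
    if np.isscalar(f):
        return complex(z)
    return z


def _model_channels(params: IdealCPEParams, f: np.ndarray):
    """(log10 |Z|, capacitive phase in degrees) of the model."""
    z = ideal_cpe_impedance(params, f)
    return np.log10(np.abs(z)), -np.degrees(np.angle(z))


def read_eis_csv(path) -> list[ImpedanceSpectrum]:
    """Read spectra from CSV with columns frequency_hz, magnitude_ohm, phase_deg, electrode_id.

    Returns one spectrum per electrode_id (original order of first appearance),
    each sorted by frequency.  Optional column `replicate` is carried through.
    """
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    spectra = []
    for eid in df["electrode_id"].drop_duplicates():
        sub = df[df["electrode_id"] == eid].sort_values("frequency_hz")
        rep = None
        if "replicate" in sub.columns and sub["replicate"].notna().any():
            rep = str(sub["replicate"].iloc[0])
        spectra.append(ImpedanceSpectrum(
            frequencies=sub["frequency_hz"].to_numpy(),
            magnitudes=sub["magnitude_ohm"].to_numpy(),
            phases=sub["phase_deg"].to_numpy(),
            electrode_id=str(eid),
            replicate=rep,
        ))
    return spectra


def write_eis_csv(path, spectra: Sequence[ImpedanceSpectrum]) -> None:
    """Write spectra to the canonical CSV dialect (comma, header, '.' decimal)."""
    frames = []
    for s in spectra:
        frames.append(pd.DataFrame({
            "frequency_hz": s.frequencies,
            "magnitude_ohm": s.magnitudes,
            "phase_deg": s.phases,
            "electrode_id": s.electrode_id,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.12g")


@dataclass
class NoiseModel:
    """Measurement noise: relative (multiplicative) magnitude sd + additive phase sd."""

    magnitude_rel_sd: float = 0.0
    phase_sd_deg: float = 0.0

    def __post_init__(self):
        if self.magnitude_rel_sd < 0 or self.phase_sd_deg < 0:
            raise ValidationError("noise standard deviations must be >= 0")


def generate_synthetic_eis(params: IdealCPEParams,
                           f_grid,
                           noise: NoiseModel | None = None,
                           seed: int | None = None,
                           electrode_id: str = "synthetic") -> ImpedanceSpectrum:
    """Synthesize a spectrum from the ideal model, optionally with noise.

    Reproducible for a fixed seed; zero noise returns the exact model curve.
    """
    f = np.sort(np.asarray(f_grid, dtype=float))
    if f.size == 0:
        raise ValidationError("frequency grid is empty")
    noise = noise or NoiseModel()
    mag, phase = 10.0 ** _model_channels(params, f)[0], _model_channels(params, f)[1]
    if noise.magnitude_rel_sd > 0 or noise.phase_sd_deg > 0:
        rng = np.random.default_rng(seed)
        mag = mag * (1.0 + noise.magnitude_rel_sd * rng.standard_normal(f.size))
        phase = phase + noise.phase_sd_deg * rng.standard_normal(f.size)
        mag = np.maximum(mag, 1e-12)
        phase = np.clip(phase, 0.0, 90.0)
    return ImpedanceSpectrum(f, mag, phase, electrode_id=electrode_id)


@dataclass
class FitDiagnostics:
    residual_log_magnitude: float
    residual_phase: float
    n_iterations: int
    m_at_bound: bool
    converged: bool
    message: str = ""


def fit_cpe(spectrum: ImpedanceSpectrum,
            min_decades: float = 2.0) -> tuple[IdealCPEParams, FitDiagnostics]:
    """Fit (m, K, R_s) to a spectrum by staged nonlinear least squares.

    Stage 1 scans m on a coarse grid (K from the low-frequency magnitudes,
    R_s from the high-frequency magnitude floor); stage 2 jointly refines all
    three parameters on equally weighted log10|Z| and phase/90 residual
    channels.  Mirrors the usual manual adjustment order (shape first, then
    the series resistance).
    """
    if spectrum.decades() < min_decades:
        raise ValidationError(
            f"spectrum spans {spectrum.decades():.2f} decades; need >= {min_decades}")
    f = spectrum.frequencies
    w = 2.0 * np.pi * f
    log_mag_data = np.log10(spectrum.magnitudes)
    phase_data = spectrum.phases

    def residual(x):
        m, logK, Rs = x
        p = IdealCPEParams(np.clip(m, _M_LO, _M_HI), 10.0 ** logK, max(Rs, 0.0))
        lm, ph = _model_channels(p, f)
        return np.concatenate([lm - log_mag_data, (ph - phase_data) / 90.0])

    # stage 1: coarse grid on m
    rs0 = max(0.0, spectrum.magnitudes[-1] * np.cos(np.deg2rad(spectrum.phases[-1])) * 0.5)
    best = None
    for m0 in np.linspace(0.05, 0.95, 19):
        # K estimate from the low-frequency half where the CPE dominates R_s
        half = slice(0, max(2, f.size // 2))
        k0 = float(np.median(np.maximum(spectrum.magnitudes[half] - rs0, 1e-9)
                             * w[half] ** m0))
        x0 = (m0, np.log10(k0), rs0)
        r = residual(x0)
        cost = float(r @ r)
        if best is None or cost < best[1]:
            best = (x0, cost)

    # stage 2: joint refinement
    res = least_squares(
        residual, best[0],
        bounds=([_M_LO, -6.0, 0.0], [_M_HI, 12.0, np.inf]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    m, logK, Rs = res.x
    n = f.size
    r = res.fun
    diag = FitDiagnostics(
        residual_log_magnitude=float(np.linalg.norm(r[:n]) / np.sqrt(n)),
        residual_phase=float(np.linalg.norm(r[n:] * 90.0) / np.sqrt(n)),
        n_iterations=int(res.nfev),
        m_at_bound=bool(m <= _M_LO * 1.5 or m >= 1.0 - 1e-5),
        converged=bool(res.success),
        message=res.message,
    )
    params = IdealCPEParams(float(np.clip(m, _M_LO, _M_HI)), float(10.0 ** logK),
                            float(Rs))
    if not res.success:
        raise FitError("CPE fit did not converge", best_params=params,
                       residual=float(np.linalg.norm(r)))
    return params, diag
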