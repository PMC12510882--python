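"""Zernike polynomial basis, wavefront composition and quality metrics.

Modes are double-indexed ``Z_n^m`` (radial order ``n``, azimuthal order
``m``) and ordered by the ANSI/OSA single index ``j = (n(n+2) + m) / 2``.
All modes are RMS-normalized over the unit pupil, so a coefficient read
directly gives that mode's contribution to the wavefront RMS in units of
the wavelength (lambda RMS), and the Euclidean norm of a coefficient
vector equals the RMS of the composed phase map.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

__all__ = [
    "ZernikeIndex",
    "Wavefront",
    "PhaseMap",
    "ansi_index",
    "from_ansi",
    "eligible_modes",
    "all_modes",
    "pupil_grid",
    "evaluate_mode",
    "compose_wavefront",
    "fit_wavefront",
    "wavefront_metrics",
    "strehl_marechal",
    "EXCLUDED_MODES",
]

#: Piston, tip, tilt and defocus: pure phase offsets or image translations,
#: carrying no information about image quality; excluded from sensing.
EXCLUDED_MODES = ((0, 0), (1, -1), (1, 1), (2, 0))


class ZernikeIndex(NamedTuple):
    """Double index of a Zernike mode."""

    n: int
    m: int

    def validate(self) -> "ZernikeIndex":
        n, m = self
        if n < 0 or abs(m) > n or (n - abs(m)) % 2 != 0:
            raise ValueError(f"invalid Zernike index (n={n}, m={m}): "
                             "require |m| <= n and n - |m| even")
        return self


def ansi_index(idx: ZernikeIndex) -> int:
    """ANSI/OSA single index ``j = (n(n+2) + m) / 2``; (4, 4) -> 14."""
    n, m = ZernikeIndex(*idx).validate()
    return (n * (n + 2) + m) // 2


def from_ansi(j: int) -> ZernikeIndex:
    """Inverse of :func:`ansi_index`."""
    if j < 0:
        raise ValueError("ANSI index must be >= 0")
    n = int((math.isqrt(8 * j + 1) - 1) // 2)
    while n * (n + 2) < 2 * j - n:
        n += 1
    m = 2 * j - n * (n + 2)
    return ZernikeIndex(n, m).validate()


def all_modes(max_n: int) -> list[ZernikeIndex]:
    """All (n, m) with n <= max_n in ANSI order (15 modes for max_n=4)."""
    modes = [ZernikeIndex(n, m)
             for n in range(max_n + 1)
             for m in range(-n, n + 1, 2)]
    return sorted(modes, key=ansi_index)


def eligible_modes(max_n: int = 4) -> list[ZernikeIndex]:
    """Modes used for aberration sensing, in ANSI order.

    All modes with ``n <= max_n`` except piston, tip, tilt and defocus.
    For ``max_n = 4`` this is the 11 sensed modes out of the first 15.
    """
    if max_n < 2:
        raise ValueError("max_n must be >= 2")
    excluded = set(EXCLUDED_MODES)
    return [idx for idx in all_modes(max_n) if tuple(idx) not in excluded]


@dataclass(frozen=True)
class Wavefront:
    """A wavefront as a sparse map of Zernike coefficients in lambda RMS."""

    coefficients: Mapping[ZernikeIndex, float] = field(default_factory=dict)
    wavelength: float = 510.0  # nm, emission

    def __post_init__(self):
        coeffs = {ZernikeIndex(*k).validate(): float(v)
                  for k, v in self.coefficients.items()}
        object.__setattr__(self, "coefficients", coeffs)

    def rms(self) -> float:
        """Wavefront RMS in lambda: the coefficient-vector norm."""
        return float(np.linalg.norm(list(self.coefficients.values()) or [0.0]))

    def amplitude(self, idx) -> float:
        return float(self.coefficients.get(ZernikeIndex(*idx), 0.0))

    def to_vector(self, modes: Sequence[ZernikeIndex]) -> np.ndarray:
        return np.array([self.amplitude(i) for i in modes], dtype=float)

    @classmethod
    def from_vector(cls, values: Iterable[float],
                    modes: Sequence[ZernikeIndex],
                    wavelength: float = 510.0) -> "Wavefront":
        coeffs = {ZernikeIndex(*i): float(v) for i, v in zip(modes, values)}
        return cls(coeffs, wavelength)

    def __add__(self, other: "Wavefront") -> "Wavefront":
        keys = set(self.coefficients) | set(other.coefficients)
        return Wavefront({k: self.amplitude(k) + other.amplitude(k) for k in keys},
                         self.wavelength)

    def __sub__(self, other: "Wavefront") -> "Wavefront":
        keys = set(self.coefficients) | set(other.coefficients)
        return Wavefront({k: self.amplitude(k) - other.amplitude(k) for k in keys},
                         self.wavelength)

    def __mul__(self, c: float) -> "Wavefront":
        return Wavefront({k: c * v for k, v in self.coefficients.items()},
                         self.wavelength)

    __rmul__ = __mul__

    # -- serialization -------------------------------------------------
    def to_json(self) -> str:
        modes = sorted(self.coefficients, key=ansi_index)
        return json.dumps({
            "wavelength_nm": self.wavelength,
            "modes": [{"n": i.n, "m": i.m,
                       "amplitude_lambda_rms": self.coefficients[i]}
                      for i in modes],
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "Wavefront":
        obj = json.loads(text)
        coeffs = {ZernikeIndex(e["n"], e["m"]): e["amplitude_lambda_rms"]
                  for e in obj["modes"]}
        return cls(coeffs, obj.get("wavelength_nm", 510.0))

    def to_text(self) -> str:
        """One mode per line: ``n m amplitude_lambda_rms``."""
        modes = sorted(self.coefficients, key=ansi_index)
        return "\n".join(f"{i.n} {i.m} {self.coefficients[i]:.9g}"
                         for i in modes) + "\n"

    @classmethod
    def from_text(cls, text: str, wavelength: float = 510.0) -> "Wavefront":
        coeffs = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            n, m, a = line.split()
            coeffs[ZernikeIndex(int(n), int(m))] = float(a)
        return cls(coeffs, wavelength)


@dataclass
class PhaseMap:
    """Phase over pupil coordinates; values outside ``mask`` are ignored."""

    values: np.ndarray
    mask: np.ndarray

    def masked(self) -> np.ndarray:
        return self.values[self.mask]

    def rms(self) -> float:
        v = self.masked()
        return float(np.sqrt(np.mean(v ** 2)))

    def peak_to_valley(self) -> float:
        v = self.masked()
        return float(v.max() - v.min())


def pupil_grid(size: int = 256) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit-pupil sampling: (rho, theta, mask) on a ``size x size`` grid.

    Pixel centers span (-1, 1); mask keeps rho <= 1.
    """
    c = (np.arange(size) - (size - 1) / 2) / (size / 2)
    x, y = np.meshgrid(c, c, indexing="xy")
    rho = np.hypot(x, y)
    theta = np.arctan2(y, x)
    return rho, theta, rho <= 1.0


def _radial_poly(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    m = abs(m)
    out = np.zeros_like(rho, dtype=float)
    for k in range((n - m) // 2 + 1):
        c = ((-1) ** k * math.factorial(n - k)
             / (math.factorial(k)
                * math.factorial((n + m) // 2 - k)
                * math.factorial((n - m) // 2 - k)))
        out += c * rho ** (n - 2 * k)
    return out


def zernike_values(idx: ZernikeIndex, rho: np.ndarray,
                   theta: np.ndarray) -> np.ndarray:
    """RMS-normalized mode values at arbitrary pupil coordinates."""
    n, m = ZernikeIndex(*idx).validate()
    r = _radial_poly(n, m, rho)
    if m == 0:
        norm = math.sqrt(n + 1)
        ang = 1.0
    else:
        norm = math.sqrt(2 * (n + 1))
        ang = np.cos(m * theta) if m > 0 else np.sin(-m * theta)
    return norm * r * ang


def evaluate_mode(idx: ZernikeIndex, grid_size: int = 256) -> PhaseMap:
    """A single RMS-normalized mode sampled over the unit pupil."""
    rho, theta, mask = pupil_grid(grid_size)
    values = zernike_values(idx, rho, theta)
    values = np.where(mask, values, 0.0)
    return PhaseMap(values, mask)


def compose_wavefront(w: Wavefront, grid_size: int = 256) -> PhaseMap:
    """Weighted sum of modes; units follow the coefficients (lambda)."""
    rho, theta, mask = pupil_grid(grid_size)
    values = np.zeros_like(rho)
    for idx, a in w.coefficients.items():
        if a != 0.0:
            values += a * zernike_values(idx, rho, theta)
    values = np.where(mask, values, 0.0)
    return PhaseMap(values, mask)


def fit_wavefront(p: PhaseMap, modes: Sequence[ZernikeIndex],
                  wavelength: float = 510.0) -> Wavefront:
    """Least-squares projection of a phase map onto a mode set."""
    modes = [ZernikeIndex(*i).validate() for i in modes]
    mask = p.mask
    if int(mask.sum()) < len(modes):
        raise ValueError("degenerate pupil mask: fewer valid pixels than modes")
    size = mask.shape[0]
    rho, theta, _ = pupil_grid(size)
    design = np.stack([zernike_values(i, rho[mask], theta[mask])
                       for i in modes], axis=1)
    coeffs, *_ = np.linalg.lstsq(design, p.values[mask], rcond=None)
    return Wavefront.from_vector(coeffs, modes, wavelength)


def strehl_marechal(rms_lambda: float) -> float:
    """Extended Marechal approximation ``exp(-(2 pi sigma)^2)``, clamped.

    Gives the conventional diffraction-limit correspondence: 0.075 lambda
    RMS distortion maps to a Strehl ratio of ~0.8.
    """
    s = math.exp(-((2 * math.pi * rms_lambda) ** 2))
    return min(max(s, 0.0), 1.0)


def wavefront_metrics(w: Wavefront, grid_size: int = 256) -> dict:
    """Scalar quality metrics: RMS, peak-to-valley, Strehl ratio.

    RMS comes from the coefficient norm (exact for the RMS-normalized
    basis); P-V is evaluated on the composed grid; Strehl uses the
    Marechal approximation on the RMS.
    """
    rms = w.rms()
    if any(a != 0.0 for a in w.coefficients.values()):
        pv = compose_wavefront(w, grid_size).peak_to_valley()
    else:
        pv = 0.0
    return {"rms": rms, "peak_to_valley": pv, "strehl": strehl_marechal(rms)}
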