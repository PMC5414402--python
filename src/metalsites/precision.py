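"""Cruickshank diffraction precision index (DPI) and error propagation.

The DPI condenses refinement statistics into a single estimate of the average
atomic coordinate uncertainty.  Two variants are provided:

* ``rfree``:        sigma(x) = sqrt(Natoms / Nrefl) * C^(-1/3) * Rfree * dmin
* ``cruickshank_obs_minus_params``:
                    sigma(x) = sqrt(Natoms / (Nobs - Nparams)) * C^(-1/3) * R * dmin

where C is the completeness as a fraction.  The second form becomes unstable
when the number of observations approaches the number of refined parameters
(anisotropic refinement at modest resolution), and an error is raised there.

Per-atom positional uncertainties are scaled from the DPI by the customary
B-factor weighting sigma_i = DPI * sqrt(B_i / <B>), and propagated to
distances in quadrature and to angles by a first-order numerical Jacobian.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .geometry import angle as _angle

__all__ = [
    "RefinementStats", "DPIResult", "cruickshank_dpi", "atom_sigma",
    "distance_esd", "angle_esd", "format_with_esd", "parse_value_esd",
]


@dataclass
class RefinementStats:
    """Refinement statistics feeding the DPI (one crystallographic Table-1 row)."""

    r_factor: float | None = None
    r_free: float | None = None
    dmin: float | None = None
    completeness: float | None = None
    n_reflections: int | None = None
    n_observations: int | None = None
    n_params: int | None = None
    n_atoms: int | None = None

    def __post_init__(self) -> None:
        for name in ("r_factor", "r_free"):
            v = getattr(self, name)
            if v is not None and not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} must be a fraction in (0, 1)")
        if self.dmin is not None and self.dmin <= 0:
            raise ValueError("dmin must be positive")
        if self.completeness is not None and not 0.0 < self.completeness <= 1.0:
            raise ValueError("completeness must be a fraction in (0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "RefinementStats":
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown refinement-stats keys: {sorted(unknown)}")
        d = dict(d)
        # accept percentages for convenience, as printed in data tables
        for key in ("completeness", "r_factor", "r_free"):
            if key in d and d[key] is not None and d[key] > 1.0:
                d[key] = d[key] / 100.0
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RefinementStats":
        text = Path(path).read_text()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            import yaml
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a key-value mapping")
        return cls.from_dict(data)


@dataclass
class DPIResult:
    dpi: float
    variant: str
    inputs: dict

    def as_dict(self) -> dict:
        return asdict(self)


def cruickshank_dpi(stats: RefinementStats, variant: str = "rfree") -> DPIResult:
    """Diffraction precision index in Angstroms.

    ``variant='rfree'`` uses the free-R formulation (default; robust);
    ``variant='cruickshank_obs_minus_params'`` uses the original
    observations-minus-parameters denominator and raises when that
    denominator is not safely positive.
    """
    if variant == "rfree":
        needed = {"n_atoms": stats.n_atoms, "n_reflections": stats.n_reflections,
                  "completeness": stats.completeness, "r_free": stats.r_free,
                  "dmin": stats.dmin}
        missing = [k for k, v in needed.items() if v is None]
        if missing:
            raise ValueError(f"rfree DPI variant requires {missing}")
        dpi = (math.sqrt(stats.n_atoms / stats.n_reflections)
               * stats.completeness ** (-1.0 / 3.0)
               * stats.r_free * stats.dmin)
    elif variant == "cruickshank_obs_minus_params":
        needed = {"n_atoms": stats.n_atoms, "n_observations": stats.n_observations,
                  "n_params": stats.n_params, "completeness": stats.completeness,
                  "r_factor": stats.r_factor, "dmin": stats.dmin}
        missing = [k for k, v in needed.items() if v is None]
        if missing:
            raise ValueError(f"obs-minus-params DPI variant requires {missing}")
        dof = stats.n_observations - stats.n_params
        if dof <= 0:
            raise ValueError(
                "DPI unstable: observations do not exceed refined parameters "
                f"({stats.n_observations} - {stats.n_params} = {dof})")
        dpi = (math.sqrt(stats.n_atoms / dof)
               * stats.completeness ** (-1.0 / 3.0)
               * stats.r_factor * stats.dmin)
    else:
        raise ValueError(f"unknown DPI variant {variant!r}")
    return DPIResult(dpi=float(dpi), variant=variant,
                     inputs={k: v for k, v in asdict(stats).items()
                             if v is not None})


def atom_sigma(dpi: float, b_iso: float, b_avg: float) -> float:
    """B-weighted per-atom positional uncertainty: dpi * sqrt(B / <B>)."""
    if dpi < 0:
        raise ValueError("dpi must be non-negative")
    if b_iso <= 0 or b_avg <= 0:
        raise ValueError("B factors must be positive")
    return float(dpi * math.sqrt(b_iso / b_avg))


def distance_esd(sigma_a: float, sigma_b: float) -> float:
    """Quadrature esd of a distance between atoms with isotropic sigmas."""
    if sigma_a < 0 or sigma_b < 0:
        raise ValueError("sigmas must be non-negative")
    return float(math.hypot(sigma_a, sigma_b))


def angle_esd(positions: np.ndarray, sigmas: np.ndarray,
              step: float = 1e-5) -> float:
    """First-order propagated esd (degrees) of the angle p0-p1-p2.

    ``positions`` is a 3x3 array ordered (arm_a, vertex, arm_b); ``sigmas``
    are the three isotropic positional esds in the same order.  The Jacobian
    of the angle with respect to the nine coordinates is formed by central
    differences.
    """
    pos = np.asarray(positions, dtype=float).reshape(3, 3)
    sig = np.asarray(sigmas, dtype=float).reshape(3)
    if np.any(sig < 0):
        raise ValueError("sigmas must be non-negative")
    a, v, b = pos
    if np.linalg.norm(a - v) < 1e-9 or np.linalg.norm(b - v) < 1e-9:
        raise ValueError("degenerate angle geometry")
    base = _angle(a, v, b)
    if base < 1e-6 or base > 180.0 - 1e-6:
        raise ValueError("degenerate (collinear) angle geometry")
    var = 0.0
    for i in range(3):
        for j in range(3):
            dp = pos.copy()
            dm = pos.copy()
            dp[i, j] += step
            dm[i, j] -= step
            deriv = (_angle(*dp) - _angle(*dm)) / (2.0 * step)
            var += (deriv * sig[i]) ** 2
    return float(math.sqrt(var))


def _round_sig(x: float, sig: int = 1) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def format_with_esd(value: float, esd: float) -> str:
    """Crystallographic ``value (esd)`` notation.

    The esd is rounded to one significant figure and shown in parentheses in
    units of the value's last quoted digit: (2.252, 0.08) -> ``"2.25 (8)"``,
    (41.3, 2.1) -> ``"41 (2)"``.
    """
    if esd <= 0:
        raise ValueError("esd must be positive")
    e = _round_sig(esd, 1)
    exp = int(math.floor(math.log10(e)))
    # re-round in case 0.096 -> 0.1 changed the decade
    e = _round_sig(e, 1)
    exp = int(math.floor(math.log10(e)))
    ndec = max(0, -exp)
    paren = int(round(e / 10.0 ** exp)) if exp < 0 else int(round(e))
    val_s = f"{value:.{ndec}f}"
    return f"{val_s} ({paren})"


def parse_value_esd(text: str) -> tuple[float, float]:
    """Inverse of :func:`format_with_esd`: ``"2.25 (8)"`` -> (2.25, 0.08)."""
    text = text.strip().rstrip("°A ")
    if "(" not in text or not text.endswith(")"):
        raise ValueError(f"not a value (esd) string: {text!r}")
    val_s, paren = text[:-1].split("(")
    val_s = val_s.strip()
    value = float(val_s)
    digits = paren.strip()
    if "." in val_s:
        ndec = len(val_s.split(".")[1])
        esd = float(digits) * 10.0 ** (-ndec)
    else:
        esd = float(digits)
    return value, esd
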