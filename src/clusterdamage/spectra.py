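"""Energy-imparted frequency spectra for the 5 x 5 nm cylindrical site.

An :class:`EnergySpectrum` holds the differential distribution ``dF/de`` of
energy imparted per event to the target volume, normalized to unit integral
(trapezoid rule on the stored grid), together with radiation metadata (label,
LET, frequency-mean specific energy) and the site descriptor.

Spectra are read and written as '#'-commented two-column text; a parametric
generator provides exponential integral spectra (``F(>e) = exp(-e/e0)``),
the form that fits low-LET electron energy-imparted distributions at this
site size.  The bundled presets are synthetic stand-ins labelled by the
radiation quality they emulate; they are not fits to published Monte-Carlo
spectra.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence

import numpy as np

from .core_model import ParameterError

__all__ = [
    "SpectrumFormatError",
    "EnergySpectrum",
    "EV_TO_J",
    "site_mass_kg",
    "DEFAULT_SITE_MASS_KG",
    "read_spectrum",
    "write_spectrum",
    "exponential_spectrum",
    "mean_specific_energy",
    "mix_spectra",
    "PRESETS",
    "make_preset",
]

EV_TO_J = 1.602176634e-19

#: renormalisation tolerance on read: integrals off by less than this are
#: silently renormalised, larger deviations are format errors.
_INTEGRAL_TOL = 0.01


class SpectrumFormatError(ValueError):
    """Raised for malformed spectrum files or invalid spectrum data."""


def site_mass_kg(diameter_nm: float = 5.0, height_nm: float = 5.0,
                 density_kg_m3: float = 1000.0) -> float:
    """Mass of a right-cylinder site of unit-density material (kg)."""
    r = diameter_nm * 1e-9 / 2.0
    h = height_nm * 1e-9
    return math.pi * r * r * h * density_kg_m3


#: ~9.8e-23 kg for the default 5 nm x 5 nm cylinder
DEFAULT_SITE_MASS_KG = site_mass_kg()


@dataclass
class EnergySpectrum:
    """Normalized energy-imparted frequency distribution ``dF/de``.

    ``grid`` is strictly increasing in eV; ``density`` is the probability
    density per eV with unit trapezoid integral.  ``meta`` carries radiation
    metadata: conventional keys are ``label``, ``let_kev_um``, ``z_f_gy``,
    ``site_diameter_nm``, ``site_height_nm``, ``site_mass_kg``.
    """

    grid: np.ndarray
    density: np.ndarray
    meta: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.grid.ndim != 1 or self.grid.shape != self.density.shape:
            raise SpectrumFormatError("grid and density must be equal-length 1-D")
        if self.grid.size < 2:
            raise SpectrumFormatError("spectrum needs at least two grid points")
        if np.any(self.grid < 0):
            raise SpectrumFormatError("grid energies must be non-negative")
        if np.any(np.diff(self.grid) <= 0):
            raise SpectrumFormatError("grid must be strictly increasing")
        if np.any(self.density < 0):
            raise SpectrumFormatError("density must be non-negative")
        integral = float(np.trapezoid(self.density, self.grid))
        if abs(integral - 1.0) > 1e-6:
            raise SpectrumFormatError(
                f"density must integrate to 1 (got {integral!r}); "
                "use .renormalized() or the readers, which renormalise "
                "small deviations"
            )

    @classmethod
    def from_unnormalized(cls, grid, density, meta=None,
                          tol: float = _INTEGRAL_TOL) -> "EnergySpectrum":
        """Build a spectrum, renormalising an integral within ``tol`` of 1.

        ``tol=None`` renormalises unconditionally (used by the parametric
        constructors, whose truncation to a finite grid is deliberate).
        """
        grid = np.asarray(grid, dtype=float)
        density = np.asarray(density, dtype=float)
        if np.any(density < 0):
            raise SpectrumFormatError("density must be non-negative")
        integral = float(np.trapezoid(density, grid))
        if integral <= 0:
            raise SpectrumFormatError("density integrates to zero")
        if tol is not None and abs(integral - 1.0) >= tol:
            raise SpectrumFormatError(
                f"density integrates to {integral!r}, off by >= {tol:.0%}"
            )
        return cls(grid, density / integral, dict(meta or {}))

    def mean_energy_ev(self) -> float:
        """Frequency-mean energy imparted per event (eV)."""
        return float(np.trapezoid(self.grid * self.density, self.grid))

    @property
    def let_kev_um(self) -> float | None:
        v = self.meta.get("let_kev_um")
        return float(v) if v is not None else None

    def z_f_gy(self, site_mass: float | None = None) -> float:
        """Frequency-mean specific energy (Gy): metadata if present, else
        computed from the mean energy and the site mass."""
        v = self.meta.get("z_f_gy")
        if v is not None:
            return float(v)
        mass = site_mass
        if mass is None:
            m = self.meta.get("site_mass_kg")
            mass = float(m) if m is not None else DEFAULT_SITE_MASS_KG
        return mean_specific_energy(self, mass)


def write_spectrum(spec: EnergySpectrum, path) -> None:
    """Write a spectrum as '#'-commented metadata plus two-column text."""
    path = Path(path)
    lines = []
    for key, value in spec.meta.items():
        lines.append(f"# {key}: {value}")
    lines.append("# columns: energy_ev density_per_ev")
    for e, d in zip(spec.grid, spec.density):
        lines.append(f"{float(e)!r}\t{float(d)!r}")
    path.write_text("\n".join(lines) + "\n")


def read_spectrum(path) -> EnergySpectrum:
    """Read a spectrum file written by :func:`write_spectrum`.

    Metadata lines are ``# key: value``; numeric values are parsed as
    floats.  Densities must be non-negative and the grid monotone; an
    integral deviating from one by less than 1% is renormalised, larger
    deviations raise :class:`SpectrumFormatError` naming the file.
    """
    path = Path(path)
    meta: Dict[str, object] = {}
    grid: List[float] = []
    density: List[float] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                key = key.strip()
                value = value.strip()
                if key == "columns":
                    continue
                try:
                    meta[key] = float(value)
                except ValueError:
                    meta[key] = value
            continue
        parts = line.split()
        if len(parts) != 2:
            raise SpectrumFormatError(
                f"{path}:{lineno}: expected two columns, got {raw!r}"
            )
        try:
            e, d = float(parts[0]), float(parts[1])
        except ValueError:
            raise SpectrumFormatError(
                f"{path}:{lineno}: non-numeric entry in {raw!r}"
            ) from None
        if d < 0:
            raise SpectrumFormatError(
                f"{path}:{lineno}: negative density {d!r}"
            )
        if grid and e <= grid[-1]:
            raise SpectrumFormatError(
                f"{path}:{lineno}: grid not strictly increasing at {e!r}"
            )
        grid.append(e)
        density.append(d)
    if len(grid) < 2:
        raise SpectrumFormatError(f"{path}: fewer than two data rows")
    try:
        return EnergySpectrum.from_unnormalized(grid, density, meta)
    except SpectrumFormatError as exc:
        raise SpectrumFormatError(f"{path}: {exc}") from None


def exponential_spectrum(epsilon0: float, grid_max: float | None = None,
                         n_points: int = 400,
                         meta: Mapping[str, object] | None = None
                         ) -> EnergySpectrum:
    """Spectrum with exponential integral form ``F(>e) = exp(-e/e0)``.

    The density is ``(1/e0) exp(-e/e0)`` on ``[0, grid_max]`` (default
    ``15 * e0``), renormalised on the truncated grid.
    """
    if epsilon0 <= 0:
        raise ParameterError(f"epsilon0 must be positive, got {epsilon0!r}")
    if grid_max is None:
        grid_max = 15.0 * epsilon0
    grid = np.linspace(0.0, grid_max, n_points)
    density = np.exp(-grid / epsilon0) / epsilon0
    return EnergySpectrum.from_unnormalized(grid, density, meta, tol=None)


def mean_specific_energy(spec: EnergySpectrum, site_mass: float) -> float:
    """Frequency-mean specific energy ``z_F`` in Gy.

    Mean energy imparted per event (eV, converted to joules) divided by the
    site mass in kg.
    """
    if site_mass <= 0:
        raise ParameterError(f"site_mass must be positive, got {site_mass!r}")
    return spec.mean_energy_ev() * EV_TO_J / site_mass


def mix_spectra(specs: Sequence[EnergySpectrum],
                weights: Sequence[float]) -> EnergySpectrum:
    """Pointwise weighted mixture of spectra on a merged grid.

    A generic utility for combining components (for instance direct-hit and
    delta-ray contributions computed separately); weights must be
    non-negative and sum to one.
    """
    if len(specs) != len(weights) or not specs:
        raise ParameterError("specs and weights must be equal-length, non-empty")
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ParameterError("weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ParameterError(f"weights must sum to 1, got {w.sum()!r}")
    merged = np.unique(np.concatenate([s.grid for s in specs]))
    density = np.zeros_like(merged)
    for s, wi in zip(specs, w):
        density += wi * np.interp(merged, s.grid, s.density, left=0.0, right=0.0)
    meta = {"label": "mixture", "components": "+".join(
        str(s.meta.get("label", "unnamed")) for s in specs)}
    return EnergySpectrum.from_unnormalized(merged, density, meta, tol=None)


#: Synthetic exponential presets labelled by the radiation quality they
#: emulate.  epsilon0 (eV) rises with ionization density: sub-keV/um
#: electrons deposit a few tens of eV per event at a 5 nm site, while
#: stopping ions deposit hundreds.  LET metadata matches the radiation
#: labels; these are demonstration inputs, not fitted spectra.
PRESETS: Mapping[str, Dict[str, float]] = {
    "electron-100keV-like": {"epsilon0": 45.0, "let_kev_um": 0.5},
    "he-1MeVu-like": {"epsilon0": 300.0, "let_kev_um": 104.0},
    "c12-10MeVu-like": {"epsilon0": 380.0, "let_kev_um": 166.0},
    "c12-1000MeVu-like": {"epsilon0": 60.0, "let_kev_um": 8.0},
}


def make_preset(name: str, n_points: int = 400) -> EnergySpectrum:
    """Build a synthetic preset spectrum by name (see :data:`PRESETS`)."""
    if name not in PRESETS:
        raise ParameterError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    params = PRESETS[name]
    spec = exponential_spectrum(
        params["epsilon0"], n_points=n_points,
        meta={
            "label": name,
            "let_kev_um": params["let_kev_um"],
            "synthetic": "exponential stand-in, not a fitted spectrum",
            "site_diameter_nm": 5.0,
            "site_height_nm": 5.0,
            "site_mass_kg": DEFAULT_SITE_MASS_KG,
        },
    )
    spec.meta["z_f_gy"] = mean_specific_energy(spec, DEFAULT_SITE_MASS_KG)
    return spec
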