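"""Gibbs-Thomson critical-radius theory for ice embryos.

The Gibbs-Thomson effect makes the equilibrium melting temperature of an
ice crystal depend on the curvature of its surface: small, highly curved
embryos are only in equilibrium with supercooled water.  For an embryo of
spherical or cylindrical symmetry the critical radius at supercooling
``T0 - Tr`` is

    R = A_g * M_w * sigma * T0 / (L * rho_i * (T0 - Tr))

with ``A_g = 2`` (sphere) or ``1`` (cylinder), ``M_w`` the molar mass of
water, ``sigma`` the ice-water interfacial energy, ``L`` the molar latent
heat of fusion and ``rho_i`` the ice density.  Two parameter presets are
provided: real water at ambient pressure and the TIP4P rigid water model
(whose melting point is 230.5 K).  Antifreeze proteins are thought to
exploit this relation by subdividing a growing ice front into sub-critical,
highly curved segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml
from scipy.constants import N_A

__all__ = [
    "WaterModelParams",
    "CriticalRadiusResult",
    "REAL_WATER",
    "TIP4P",
    "GEOMETRY_FACTORS",
    "critical_radius",
    "embryo_size",
    "supercooling_for_radius",
    "load_water_models",
]

#: geometry factor A_g: 2 for spherical, 1 for cylindrical symmetry
GEOMETRY_FACTORS = {"spherical": 2.0, "cylindrical": 1.0}

M_PER_ANGSTROM = 1e-10


@dataclass(frozen=True)
class WaterModelParams:
    """Thermophysical constants of one water model.

    Parameters
    ----------
    name : str
        Label used in reports and on the command line.
    M_w : float
        Molar mass of water, kg/mol.
    sigma : float
        Ice-water interfacial free energy, J/m^2.
    L : float
        Molar latent heat of fusion, J/mol.
    rho_i : float
        Ice mass density, kg/m^3.
    T0 : float
        Melting temperature at atmospheric pressure, K.
    """

    name: str
    M_w: float
    sigma: float
    L: float
    rho_i: float
    T0: float

    def __post_init__(self) -> None:
        for attr in ("M_w", "sigma", "L", "rho_i", "T0"):
            value = getattr(self, attr)
            if not value > 0:
                raise ValueError(f"{self.name}: {attr} must be strictly positive, got {value!r}")
        if not 150.0 <= self.T0 <= 400.0:
            raise ValueError(f"{self.name}: T0={self.T0} K outside the plausible range [150, 400] K")


#: Real water at 1 atm (interfacial energy 29.1 mJ/m^2, latent heat 6.02 kJ/mol).
REAL_WATER = WaterModelParams(
    name="real", M_w=0.018, sigma=29.1e-3, L=6.02e3, rho_i=917.0, T0=273.15
)

#: TIP4P rigid four-site water model; melts at 230.5 K with a weaker interface.
TIP4P = WaterModelParams(
    name="tip4p", M_w=0.018, sigma=23e-3, L=4.4e3, rho_i=944.0, T0=230.5
)


@dataclass(frozen=True)
class CriticalRadiusResult:
    """Critical embryo radius plus spherical-embryo bookkeeping.

    ``volume`` (A^3) and ``n_waters`` are populated for spherical geometry
    only; a cylinder's volume depends on its (unspecified) length.
    """

    R_m: float
    geometry: str
    supercooling: float
    params: WaterModelParams
    volume: float | None = None
    n_waters: float | None = None

    @property
    def R_angstrom(self) -> float:
        return self.R_m / M_PER_ANGSTROM


def critical_radius(
    params: WaterModelParams, supercooling: float, geometry: str = "spherical"
) -> CriticalRadiusResult:
    """Critical ice-embryo radius at the given supercooling.

    Parameters
    ----------
    params : WaterModelParams
        Water model constants.
    supercooling : float
        ``T0 - Tr`` in K; must be strictly positive (a flat interface is the
        only equilibrium at zero supercooling) and smaller than ``T0``.
    geometry : {"spherical", "cylindrical"}
        Embryo symmetry; selects the geometry factor A_g.
    """
    if geometry not in GEOMETRY_FACTORS:
        raise ValueError(f"geometry must be one of {sorted(GEOMETRY_FACTORS)}, got {geometry!r}")
    if not supercooling > 0:
        raise ValueError(
            "supercooling must be > 0: at or above the melting point the "
            "equilibrium radius is undefined (no finite embryo is stable)"
        )
    if supercooling >= params.T0:
        raise ValueError(
            f"supercooling {supercooling} K >= T0 ({params.T0} K) puts Tr at or below 0 K"
        )
    A_g = GEOMETRY_FACTORS[geometry]
    R_m = A_g * params.M_w * params.sigma * params.T0 / (params.L * params.rho_i * supercooling)
    volume = n_waters = None
    if geometry == "spherical":
        volume, n_waters = embryo_size(R_m / M_PER_ANGSTROM, params)
    return CriticalRadiusResult(
        R_m=R_m,
        geometry=geometry,
        supercooling=supercooling,
        params=params,
        volume=volume,
        n_waters=n_waters,
    )


def embryo_size(R_angstrom: float, params: WaterModelParams) -> tuple[float, float]:
    """Volume (A^3) and molecule count of a spherical embryo of radius R (A).

    The molecule count uses the ice density: n = V * rho_i * N_A / M_w.
    """
    if R_angstrom < 0:
        raise ValueError(f"radius must be non-negative, got {R_angstrom}")
    from math import pi

    volume_A3 = 4.0 / 3.0 * pi * R_angstrom**3
    volume_m3 = volume_A3 * 1e-30
    n_waters = volume_m3 * params.rho_i / params.M_w * N_A
    return volume_A3, n_waters


def supercooling_for_radius(
    R_m: float, params: WaterModelParams, geometry: str = "spherical"
) -> float:
    """Inverse of :func:`critical_radius`: supercooling at which R is critical."""
    if geometry not in GEOMETRY_FACTORS:
        raise ValueError(f"geometry must be one of {sorted(GEOMETRY_FACTORS)}, got {geometry!r}")
    if not R_m > 0:
        raise ValueError("R must be strictly positive")
    A_g = GEOMETRY_FACTORS[geometry]
    return A_g * params.M_w * params.sigma * params.T0 / (params.L * params.rho_i * R_m)


def load_water_models(path: str | Path) -> dict[str, WaterModelParams]:
    """Read custom water-model parameter sets from a YAML config.

    The file must contain a ``water_models`` mapping whose entries provide
    ``M_w``, ``sigma``, ``L``, ``rho_i`` and ``T0``::

        water_models:
          mymodel: {M_w: 0.018, sigma: 0.025, L: 5.0e3, rho_i: 930, T0: 250}
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    models = {}
    for name, entry in (cfg.get("water_models") or {}).items():
        # YAML 1.1 reads exponents like 5.0e3 as strings; coerce explicitly
        models[name] = WaterModelParams(
            name=name, **{k: float(v) for k, v in entry.items()}
        )
    return models
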