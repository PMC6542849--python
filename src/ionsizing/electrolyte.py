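"""Ion and electrolyte property models.

Activity corrections follow the semi-empirical extended Debye-Hueckel (EDH) and
Truesdell-Jones (TJ) forms

    log10(gamma) = -A z^2 sqrt(I) / (1 + B a0 sqrt(I)) + b I,

where the ``b I`` term is present only in the TJ variant.  ``I`` is the ionic
strength (equal to the concentration C for 1:1 salts and 3C for MgCl2), ``a0``
the hydrated-size parameter and ``A``, ``B`` empirical constants at 25 degC.
The salt-level coefficient uses the cation's parameters; the "true" activity
is ``a = gamma * C``.

The registry also carries per-ion transport constants: the de-hydrated
(crystallographic) diameter, the bulk electrophoretic mobility and the bulk
diffusivity, all at 25 degC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import pandas as pd

from .constants import (
    A_DEBYE_HUCKEL,
    AVOGADRO,
    B_DEBYE_HUCKEL,
    BOLTZMANN,
    ELEMENTARY_CHARGE,
    EPSILON_0,
    EPSILON_R_WATER,
    ETA_WATER,
    FARADAY,
    T_REF,
)

ActivityModel = Literal["EDH", "TJ"]

__all__ = [
    "IonSpecies",
    "ElectrolyteCondition",
    "ION_REGISTRY",
    "SALTS",
    "ionic_strength",
    "activity_coefficient",
    "activity",
    "stokes_mobility",
    "einstein_diffusivity",
    "debye_length",
    "bulk_conductivity",
    "registry_to_table",
    "registry_from_table",
]


@dataclass(frozen=True)
class IonSpecies:
    """Physical constants for one ionic species.

    Parameters
    ----------
    name : short identifier, e.g. ``"Na"``.
    z : integer valence (signed).
    d_dehydrated : de-hydrated (crystallographic) diameter, nm.
    a0 : hydrated-size activity parameter, nm.
    b : Truesdell-Jones linear coefficient, 1/M.
    mu_bulk : electrophoretic mobility at infinite dilution, m^2/(V s), 25 degC.
    D_bulk : bulk diffusivity, nm^2/ns, 25 degC.
    """

    name: str
    z: int
    d_dehydrated: float
    a0: float
    b: float
    mu_bulk: float
    D_bulk: float

    def __post_init__(self) -> None:
        if self.a0 <= 0 or self.d_dehydrated <= 0:
            raise ValueError("a0 and d_dehydrated must be positive")
        if self.b < 0:
            raise ValueError("b must be non-negative")


# a0 and b follow the standard activity tabulation for these cations; Cl- is
# never separately activity-corrected (salt-level gamma uses the cation), its
# a0/b are the conventional 0.3 nm / 0.
# Mobilities from limiting molar conductivities at 25 degC
# (lambda0, S cm^2/mol: Li+ 38.7, Na+ 50.1, K+ 73.5, Cs+ 77.3, (1/2)Mg2+ 53.1,
# Cl- 76.3; mu = lambda0 / (|z| F) per charge): CRC Handbook values.
# Diffusivities via Einstein relation D = kB T mu / (z e).
ION_REGISTRY: dict[str, IonSpecies] = {
    "Li": IonSpecies("Li", +1, 0.188, 0.38, 0.20, 4.01e-8, 1.03),
    "Na": IonSpecies("Na", +1, 0.234, 0.36, 0.06, 5.19e-8, 1.33),
    "K": IonSpecies("K", +1, 0.298, 0.33, 0.01, 7.62e-8, 1.96),
    "Cs": IonSpecies("Cs", +1, 0.334, 0.33, 0.01, 8.01e-8, 2.06),
    "Mg": IonSpecies("Mg", +2, 0.144, 0.43, 0.21, 5.50e-8, 0.706),
    "Cl": IonSpecies("Cl", -1, 0.362, 0.30, 0.00, 7.91e-8, 2.03),
}

# salt -> (cation, anion, cation stoichiometry, anion stoichiometry)
SALTS: dict[str, tuple[str, str, int, int]] = {
    "NaCl": ("Na", "Cl", 1, 1),
    "KCl": ("K", "Cl", 1, 1),
    "LiCl": ("Li", "Cl", 1, 1),
    "CsCl": ("Cs", "Cl", 1, 1),
    "MgCl2": ("Mg", "Cl", 1, 2),
}


def _lookup_salt(salt: str) -> tuple[str, str, int, int]:
    try:
        return SALTS[salt]
    except KeyError:
        raise KeyError(f"unknown salt {salt!r}; known: {sorted(SALTS)}") from None


def ionic_strength(C: float, salt: str) -> float:
    """Ionic strength in M: C for the 1:1 salts in scope, 3C for MgCl2."""
    if C < 0:
        raise ValueError("concentration must be non-negative")
    cation, anion, nu_c, nu_a = _lookup_salt(salt)
    zc = ION_REGISTRY[cation].z
    za = ION_REGISTRY[anion].z
    return 0.5 * C * (nu_c * zc**2 + nu_a * za**2)


def activity_coefficient(C: float, salt: str, model: ActivityModel = "TJ") -> float:
    """Salt-level activity coefficient from the cation's EDH/TJ parameters."""
    if C < 0:
        raise ValueError("concentration must be non-negative")
    if model not in ("EDH", "TJ"):
        raise ValueError(f"model must be 'EDH' or 'TJ', got {model!r}")
    if C == 0.0:
        return 1.0
    cation = ION_REGISTRY[_lookup_salt(salt)[0]]
    I = ionic_strength(C, salt)
    sqrt_i = math.sqrt(I)
    # a0 in Angstrom pairs with B in 1/(Angstrom sqrt(M)).
    a0_angstrom = cation.a0 * 10.0
    log10_gamma = -A_DEBYE_HUCKEL * cation.z**2 * sqrt_i / (
        1.0 + B_DEBYE_HUCKEL * a0_angstrom * sqrt_i
    )
    if model == "TJ":
        log10_gamma += cation.b * I
    return 10.0**log10_gamma


def activity(C: float, salt: str, model: ActivityModel = "TJ") -> float:
    """True activity a = gamma(C) * C, in M."""
    return activity_coefficient(C, salt, model) * C


def stokes_mobility(z: int, eta: float, d_i: float) -> float:
    """Stokes-drag mobility mu = z e / (3 pi eta d), SI.

    ``eta`` in Pa s, ``d_i`` in m.  Returns m^2/(V s), signed like ``z``.
    """
    if eta <= 0 or d_i <= 0:
        raise ValueError("viscosity and diameter must be positive")
    return z * ELEMENTARY_CHARGE / (3.0 * math.pi * eta * d_i)


def einstein_diffusivity(mu: float, T: float = T_REF) -> float:
    """Einstein relation D = kB T mu / e (per unit charge), SI."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    return BOLTZMANN * T * mu / ELEMENTARY_CHARGE


def debye_length(
    I_strength: float, T: float = T_REF, epsilon_r: float = EPSILON_R_WATER
) -> float:
    """Debye screening length in nm for ionic strength ``I_strength`` in M."""
    if I_strength <= 0:
        raise ValueError("ionic strength must be positive")
    n = 2.0 * I_strength * 1000.0 * AVOGADRO  # ions/m^3 weighted by z^2, 2I convention
    lam = math.sqrt(
        epsilon_r * EPSILON_0 * BOLTZMANN * T / (n * ELEMENTARY_CHARGE**2)
    )
    return lam * 1e9


@dataclass(frozen=True)
class ElectrolyteCondition:
    """One fully specified electrolyte condition at 25 degC.

    ``gamma`` and ``a`` are salt-level values from the cation's parameters;
    ``lambda_D`` is infinite at C = 0.
    """

    salt: str
    C: float
    model: ActivityModel = "TJ"
    I_strength: float = 0.0
    gamma: float = 1.0
    a: float = 0.0
    T: float = T_REF
    eta: float = ETA_WATER
    epsilon_r: float = EPSILON_R_WATER
    lambda_D: float = math.inf
    A_dh: float = A_DEBYE_HUCKEL
    B_dh: float = B_DEBYE_HUCKEL

    @classmethod
    def from_salt(
        cls, salt: str, C: float, model: ActivityModel = "TJ", T: float = T_REF
    ) -> "ElectrolyteCondition":
        _lookup_salt(salt)
        I = ionic_strength(C, salt)
        gamma = activity_coefficient(C, salt, model)
        lam = debye_length(I, T) if I > 0 else math.inf
        return cls(
            salt=salt, C=C, model=model, I_strength=I, gamma=gamma,
            a=gamma * C, T=T, lambda_D=lam,
        )

    @property
    def cation(self) -> IonSpecies:
        return ION_REGISTRY[_lookup_salt(self.salt)[0]]

    @property
    def anion(self) -> IonSpecies:
        return ION_REGISTRY[_lookup_salt(self.salt)[1]]

    def with_concentration(self, C: float) -> "ElectrolyteCondition":
        return ElectrolyteCondition.from_salt(self.salt, C, self.model, self.T)


def bulk_conductivity(condition: ElectrolyteCondition) -> float:
    """Ideal-dilution (Kohlrausch) conductivity sigma = F sum |z_i| c_i mu_i, S/m.

    Linear in C by construction; an infinite-dilution estimate that ignores the
    conductivity decrement at finite concentration.
    """
    _, _, nu_c, nu_a = _lookup_salt(condition.salt)
    cat, an = condition.cation, condition.anion
    c_mol_m3 = condition.C * 1000.0
    sigma = FARADAY * c_mol_m3 * (
        nu_c * abs(cat.z) * abs(cat.mu_bulk) + nu_a * abs(an.z) * abs(an.mu_bulk)
    )
    return sigma


_TABLE_COLUMNS = [
    "name", "z", "d_dehydrated_nm", "a0_nm", "b_per_M",
    "mu_m2_per_Vs", "D_nm2_per_ns",
]


def registry_to_table(path: str | Path, registry: dict[str, IonSpecies] | None = None) -> None:
    """Serialize an ion registry as a plain-text (CSV) table."""
    registry = registry if registry is not None else ION_REGISTRY
    rows = [
        (s.name, s.z, s.d_dehydrated, s.a0, s.b, s.mu_bulk, s.D_bulk)
        for s in registry.values()
    ]
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, index=False)


def registry_from_table(path: str | Path) -> dict[str, IonSpecies]:
    """Load an ion registry from the CSV written by :func:`registry_to_table`."""
    df = pd.read_csv(path)
    missing = set(_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"registry table missing columns: {sorted(missing)}")
    return {
        str(r["name"]): IonSpecies(
            str(r["name"]), int(r["z"]), float(r["d_dehydrated_nm"]),
            float(r["a0_nm"]), float(r["b_per_M"]),
            float(r["mu_m2_per_Vs"]), float(r["D_nm2_per_ns"]),
        )
        for _, r in df.iterrows()
    }
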