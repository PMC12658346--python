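"""Material definitions and photon interaction-coefficient tables.

Each :class:`Material` combines an elemental composition (mass fractions), a mass
density, and a mass attenuation table mu/rho(E) built from shipped per-element
data by the elemental mixture rule.  Dose-to-water scoring additionally uses the
water mass energy-absorption table mu_en/rho(E).

All energies are in keV, lengths in cm, densities in g/cm^3, and mass
coefficients in cm^2/g.
"""
from __future__ import annotations

import importlib.resources as _res
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Material",
    "MaterialLibrary",
    "default_library",
    "ELEMENT_Z_A",
    "AVOGADRO",
]

AVOGADRO = 6.02214076e23

#: atomic number and standard atomic weight of the elements we ship tables for
ELEMENT_Z_A = {
    "H": (1, 1.008), "C": (6, 12.011), "N": (7, 14.007), "O": (8, 15.999),
    "Si": (14, 28.085), "Ar": (18, 39.948), "Fe": (26, 55.845),
    "Ir": (77, 192.217),
}

E_MIN_KEV, E_MAX_KEV = 10.0, 1400.0


def _load_element_tables() -> dict[str, tuple[np.ndarray, np.ndarray]]:
    path = _res.files("hamdose.data") / "mu_elements.csv"
    df = pd.read_csv(path, comment="#")
    out = {}
    for el, grp in df.groupby("element"):
        g = grp.sort_values("energy_keV")
        out[el] = (g["energy_keV"].to_numpy(float), g["mu_over_rho"].to_numpy(float))
    return out


def _load_two_column(name: str) -> tuple[np.ndarray, np.ndarray]:
    path = _res.files("hamdose.data") / name
    df = pd.read_csv(path, comment="#")
    arr = df.to_numpy(float)
    return arr[:, 0], arr[:, 1]


def _loglog_interp(e_query, e_tab, y_tab):
    return np.exp(np.interp(np.log(e_query), np.log(e_tab), np.log(y_tab)))


@dataclass(frozen=True)
class Material:
    """A transport medium: composition, density, and attenuation table."""

    name: str
    composition: dict[str, float]  # element -> mass fraction
    density: float  # g/cm^3
    _mu_e: np.ndarray = field(repr=False, default=None)
    _mu_v: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"mass fractions of {self.name} sum to {total}, not 1")
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self._mu_e is None:
            elements = _load_element_tables()
            grids = [elements[el][0] for el in self.composition]
            e = np.unique(np.concatenate(grids))
            mu = np.zeros_like(e)
            for el, w in self.composition.items():
                ee, mm = elements[el]
                mu += w * _loglog_interp(e, ee, mm)
            object.__setattr__(self, "_mu_e", e)
            object.__setattr__(self, "_mu_v", mu)

    @property
    def electrons_per_gram(self) -> float:
        return AVOGADRO * sum(
            w * ELEMENT_Z_A[el][0] / ELEMENT_Z_A[el][1]
            for el, w in self.composition.items()
        )

    def mu_over_rho(self, energy_keV) -> np.ndarray:
        """Total mass attenuation coefficient (with coherent), log-log interpolated."""
        e = np.asarray(energy_keV, float)
        if np.any(e < E_MIN_KEV) or np.any(e > 1500.0):
            raise ValueError("energy outside tabulated range")
        return _loglog_interp(e, self._mu_e, self._mu_v)

    def mu_linear(self, energy_keV) -> np.ndarray:
        """Linear attenuation coefficient mu (1/cm)."""
        return self.density * self.mu_over_rho(energy_keV)


def _water_mu_en():
    return _load_two_column("mu_en_water.csv")


def _coherent_fraction_water():
    return _load_two_column("coherent_fraction_water.csv")


@dataclass(frozen=True)
class MaterialLibrary:
    """The fixed set of media used by the applicator model.

    Transport media (indexable by the MC kernel): water, air, silicone, HDPE.
    First-flight-only media (source self-attenuation): iridium, steel.
    """

    water: Material
    air: Material
    silicone: Material
    hdpe: Material
    iridium: Material
    steel: Material

    #: kernel material ids for the transport media
    TRANSPORT_ORDER = ("water", "air", "silicone", "hdpe")

    def transport_materials(self) -> list[Material]:
        return [getattr(self, n) for n in self.TRANSPORT_ORDER]

    def mu_en_water(self, energy_keV) -> np.ndarray:
        e_tab, v_tab = _water_mu_en()
        return _loglog_interp(np.asarray(energy_keV, float), e_tab, v_tab)

    def coherent_fraction(self, energy_keV) -> np.ndarray:
        e_tab, v_tab = _coherent_fraction_water()
        return np.interp(np.asarray(energy_keV, float), e_tab, v_tab)


def default_library() -> MaterialLibrary:
    """Media of the HAM treatment model.

    Silicone flap is C2H6OSi at 1.09 g/cm^3 and the catheters are HDPE (C2H4)
    at 0.97 g/cm^3; capsule and cable steel is approximated as pure iron.
    """
    return MaterialLibrary(
        water=Material("water", {"H": 0.1119, "O": 0.8881}, 0.998),
        air=Material("air", {"N": 0.7552, "O": 0.2320, "Ar": 0.0128}, 1.205e-3),
        silicone=Material(
            "silicone",
            {"C": 0.32395, "H": 0.08156, "O": 0.21575, "Si": 0.37874},
            1.09,
        ),
        hdpe=Material("hdpe", {"C": 0.85628, "H": 0.14372}, 0.97),
        iridium=Material("iridium", {"Ir": 1.0}, 22.42),
        steel=Material("steel", {"Fe": 1.0}, 8.0),
    )
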