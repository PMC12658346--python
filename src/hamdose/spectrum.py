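"""Discrete Ir-192 photon emission spectrum."""
from __future__ import annotations

import importlib.resources as _res
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GammaSpectrum", "ir192_spectrum"]


@dataclass(frozen=True)
class GammaSpectrum:
    """A discrete line spectrum: energies (keV) and intensities (photons/decay).

    Lines are sorted by energy; the cumulative sampling table is normalized to 1.
    """

    energies: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.energies, float)
        i = np.asarray(self.intensities, float)
        if e.size == 0:
            raise ValueError("empty spectrum")
        if e.shape != i.shape:
            raise ValueError("energies and intensities differ in length")
        if np.any(i <= 0):
            raise ValueError("all intensities must be positive")
        if np.any(e < 60.0) or np.any(e > 1400.0):
            raise ValueError("line energies must lie in [60, 1400] keV")
        if np.any(np.diff(e) < 0):
            raise ValueError("lines must be sorted by energy")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "intensities", i)

    @property
    def cdf(self) -> np.ndarray:
        c = np.cumsum(self.intensities)
        return c / c[-1]

    @property
    def mean_energy(self) -> float:
        """Intensity-weighted mean line energy (keV)."""
        return float(np.average(self.energies, weights=self.intensities))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        idx = np.searchsorted(self.cdf, rng.random(n))
        return self.energies[idx]

    @classmethod
    def from_csv(cls, path) -> "GammaSpectrum":
        df = pd.read_csv(path, comment="#").sort_values("energy_keV")
        return cls(df["energy_keV"].to_numpy(float), df["intensity"].to_numpy(float))


def ir192_spectrum() -> GammaSpectrum:
    """The shipped Ir-192 line table (gammas and K x-rays above 60 keV)."""
    return GammaSpectrum.from_csv(_res.files("hamdose.data") / "ir192_spectrum.csv")
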