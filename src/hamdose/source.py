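"""Ir-192 source capsule model and decay-photon sampling.

The capsule model is a configurable simplification of the microSelectron v3:
a cylindrical iridium core inside a stainless-steel cylindrical capsule, with a
steel drive cable extending from the proximal end.  Dimensions approximate the
manufacturer drawing and are all adjustable.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectrum import GammaSpectrum

__all__ = ["SourceGeometry", "sample_decay_photons", "orthonormal_basis"]


@dataclass(frozen=True)
class SourceGeometry:
    """Simplified cylindrical source: Ir core, steel capsule, steel cable (cm)."""

    active_length: float = 0.35
    active_radius: float = 0.0325
    capsule_outer_radius: float = 0.0425
    capsule_length: float = 0.50
    capsule_material: str = "steel"
    cable_length: float = 10.0
    cable_radius: float = 0.035
    cable_material: str = "steel"

    def __post_init__(self):
        dims = (self.active_length, self.active_radius, self.capsule_outer_radius,
                self.capsule_length, self.cable_length, self.cable_radius)
        if any(d <= 0 for d in dims):
            raise ValueError("all source dimensions must be positive")
        if self.active_radius >= self.capsule_outer_radius:
            raise ValueError("active_radius must be smaller than capsule_outer_radius")


def orthonormal_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors perpendicular to ``axis`` (and to each other)."""
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    helper = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(a, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    return e1, e2


def sample_decay_photons(
    n: int,
    spectrum: GammaSpectrum,
    geometry: SourceGeometry,
    position: np.ndarray = (0.0, 0.0, 0.0),
    axis: np.ndarray = (0.0, 0.0, 1.0),
    rng: np.random.Generator | None = None,
):
    """Sample primary photons from the active cylinder of a posed source.

    Positions are uniform over the active cylinder volume, directions isotropic
    on the unit sphere, energies drawn from the discrete line spectrum in
    proportion to intensity.

    Returns ``(positions (n,3), directions (n,3), energies (n,))``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    pos0 = np.asarray(position, float)
    ax = np.asarray(axis, float)
    ax = ax / np.linalg.norm(ax)
    e1, e2 = orthonormal_basis(ax)

    r = geometry.active_radius * np.sqrt(rng.random(n))
    phi = 2 * np.pi * rng.random(n)
    u = geometry.active_length * (rng.random(n) - 0.5)
    pos = (pos0[None, :] + np.outer(u, ax)
           + np.outer(r * np.cos(phi), e1) + np.outer(r * np.sin(phi), e2))

    ct = 2 * rng.random(n) - 1
    st = np.sqrt(1 - ct**2)
    psi = 2 * np.pi * rng.random(n)
    dirs = np.column_stack([st * np.cos(psi), st * np.sin(psi), ct])

    return pos, dirs, spectrum.sample(n, rng)
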