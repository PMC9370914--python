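"""Primitive domain types shared by every stage of the pipeline.

The package models near-infrared transillumination imaging of a turbid
medium (body tissue or a tissue-simulating lipid emulsion).  Light
transport in such a medium is diffusive and is summarised by two bulk
optical parameters:

``mu_s_prime``
    reduced scattering coefficient, mm^-1 (tissue-like value 1.0),
``mu_a``
    absorption coefficient, mm^-1 (tissue-like value 0.01).

From these the effective attenuation coefficient
``kappa_d = sqrt(3 * mu_a * (mu_s_prime + mu_a))`` follows; it is the
decay rate of the diffuse fluence and appears in the exponential tail of
the depth-dependent point spread function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "OpticalProperties",
    "ImageGrid",
    "TransilluminationImage",
    "kappa_d",
    "as_optical",
]


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical parameters of the turbid medium (both in mm^-1)."""

    mu_s_prime: float
    mu_a: float

    def __post_init__(self):
        if not np.isfinite(self.mu_s_prime) or self.mu_s_prime <= 0:
            raise InvalidParameterError(
                f"mu_s_prime must be positive and finite, got {self.mu_s_prime}"
            )
        if not np.isfinite(self.mu_a) or self.mu_a < 0:
            raise InvalidParameterError(
                f"mu_a must be non-negative and finite, got {self.mu_a}"
            )

    @property
    def kappa_d(self) -> float:
        """Effective attenuation coefficient, mm^-1."""
        return math.sqrt(3.0 * self.mu_a * (self.mu_s_prime + self.mu_a))

    @property
    def mu_t(self) -> float:
        """Total transport attenuation mu_s' + mu_a, mm^-1."""
        return self.mu_s_prime + self.mu_a


def as_optical(optical) -> OpticalProperties:
    """Coerce an ``OpticalProperties`` or a ``(mu_s_prime, mu_a)`` pair."""
    if isinstance(optical, OpticalProperties):
        return optical
    mu_s_prime, mu_a = optical
    return OpticalProperties(float(mu_s_prime), float(mu_a))


def kappa_d(optical) -> float:
    """Effective attenuation ``sqrt(3 mu_a (mu_s' + mu_a))`` in mm^-1."""
    return as_optical(optical).kappa_d


@dataclass(frozen=True)
class ImageGrid:
    """A regular pixel raster.

    Coordinates are 0-based, row-major, y pointing down.  Pixel centers
    sit at ``(index + 0.5) * pitch`` millimetres so that integer pixel
    *edges* fall on multiples of the pitch.
    """

    n_rows: int
    n_cols: int
    pitch: float  # mm per pixel

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise InvalidParameterError("grid must have at least one pixel")
        if not np.isfinite(self.pitch) or self.pitch <= 0:
            raise InvalidParameterError(f"pitch must be positive, got {self.pitch}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def height_mm(self) -> float:
        return self.n_rows * self.pitch

    @property
    def width_mm(self) -> float:
        return self.n_cols * self.pitch

    def x_centers(self) -> np.ndarray:
        """Column pixel-center coordinates in mm."""
        return (np.arange(self.n_cols) + 0.5) * self.pitch

    def y_centers(self) -> np.ndarray:
        """Row pixel-center coordinates in mm."""
        return (np.arange(self.n_rows) + 0.5) * self.pitch


@dataclass
class TransilluminationImage:
    """A 2D relative-intensity image (background ~ 1 after normalisation).

    ``provenance`` records how the image came to be: ``"synthetic"``,
    ``"raw"`` or ``"background_removed"``.  ``mask`` (optional) marks
    pixels invalidated during background removal.
    """

    values: np.ndarray
    grid: ImageGrid
    provenance: str = "synthetic"
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidParameterError("image values must be 2D")
        if self.values.shape != self.grid.shape:
            raise InvalidParameterError(
                f"image shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    def copy_with(self, values: np.ndarray, provenance: str | None = None
                  ) -> "TransilluminationImage":
        return TransilluminationImage(
            values=np.asarray(values, dtype=float),
            grid=self.grid,
            provenance=self.provenance if provenance is None else provenance,
            mask=None if self.mask is None else self.mask.copy(),
        )
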