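"""Visual-field geometry: mapping between degrees and grid indices.

The model operates on a rectangular field of view (default 40° wide by 30°
high) with its origin at the center, discretised at a fixed number of
neurons per degree.  All maps in the model share this convention for their
retinotopic (and head-centered) axes, so the degree <-> index mapping lives
in one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FieldGeometry", "gaussian_blob"]


@dataclass(frozen=True)
class FieldGeometry:
    """Spatial layout of a rate map.

    Grid axes run ``x`` (horizontal, width) and ``y`` (vertical, height) in
    degrees of visual angle, symmetric about the origin at the field
    center.  Arrays are indexed ``[y, x]`` (row-major image convention).
    """

    width_deg: float = 40.0
    height_deg: float = 30.0
    neurons_per_deg: float = 1.0

    def __post_init__(self) -> None:
        if self.width_deg <= 0 or self.height_deg <= 0:
            raise ValueError("field dimensions must be positive")
        if self.neurons_per_deg <= 0:
            raise ValueError("neurons_per_deg must be positive")

    @property
    def nx(self) -> int:
        return int(round(self.width_deg * self.neurons_per_deg)) + 1

    @property
    def ny(self) -> int:
        return int(round(self.height_deg * self.neurons_per_deg)) + 1

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def x_deg(self) -> np.ndarray:
        """Horizontal coordinate of every column, degrees."""
        return (np.arange(self.nx) - (self.nx - 1) / 2) / self.neurons_per_deg

    @property
    def y_deg(self) -> np.ndarray:
        """Vertical coordinate of every row, degrees."""
        return (np.arange(self.ny) - (self.ny - 1) / 2) / self.neurons_per_deg

    def to_index(self, x: float, y: float) -> tuple[int, int]:
        """Nearest grid node ``(iy, ix)`` for a position in degrees."""
        ix = int(round(x * self.neurons_per_deg + (self.nx - 1) / 2))
        iy = int(round(y * self.neurons_per_deg + (self.ny - 1) / 2))
        return iy, ix

    def to_deg(self, iy: int, ix: int) -> tuple[float, float]:
        """Position in degrees of grid node ``(iy, ix)``."""
        x = (ix - (self.nx - 1) / 2) / self.neurons_per_deg
        y = (iy - (self.ny - 1) / 2) / self.neurons_per_deg
        return x, y

    def contains(self, x: float, y: float) -> bool:
        return (abs(x) <= self.width_deg / 2) and (abs(y) <= self.height_deg / 2)

    def check_inside(self, x: float, y: float, what: str = "position") -> None:
        if abs(x) > self.width_deg / 2:
            raise ValueError(
                f"{what} x={x:g}° outside field half-width "
                f"±{self.width_deg / 2:g}°"
            )
        if abs(y) > self.height_deg / 2:
            raise ValueError(
                f"{what} y={y:g}° outside field half-height "
                f"±{self.height_deg / 2:g}°"
            )


def gaussian_blob(
    geometry: FieldGeometry,
    x: float,
    y: float,
    sigma_deg: float,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Isotropic Gaussian activity blob centered at ``(x, y)`` degrees.

    Positions outside the field are allowed; the visible tail is rendered
    and the rest is clipped by the field border.
    """
    xs = geometry.x_deg[None, :] - x
    ys = geometry.y_deg[:, None] - y
    return amplitude * np.exp(-(xs**2 + ys**2) / (2.0 * sigma_deg**2))
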