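"""Two-chamber transwell geometry and the uniform finite-volume mesh.

The Boyden invasion assay is reduced to one space dimension: a unit
interval split by a zero-thickness semi-permeable membrane into a lower
chamber (neutrophil side) and an upper chamber (tumor side).  A
matrigel/ECM band straddles the membrane, and an injection subregion
marks where exogenous DNase I (or other agents) is supplied.

Conventions
-----------
* lower chamber = ``[x_min, x_membrane)``; upper chamber = ``(x_membrane, x_max]``.
* The membrane is a cell *face*, never a cell: ``x_membrane`` must land
  exactly on a face of the mesh.
* Region membership is decided by cell centers with a half-open
  ``[a, b)`` convention at shared boundaries, so masks are unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Geometry", "Grid", "build_grid", "region_mask", "ConfigurationError"]


class ConfigurationError(ValueError):
    """A configuration value violates a structural precondition."""


@dataclass(frozen=True)
class Geometry:
    """Dimensionless transwell layout.

    Parameters
    ----------
    x_min, x_max : float
        Domain bounds (default unit interval).
    x_membrane : float
        Position of the semi-permeable membrane face.
    ecm_interval : tuple of float
        Closed interval occupied by the ECM band ``S``; must contain the
        membrane in its interior.
    injection_interval : tuple of float
        Subregion where injected agents (DNase I) are sourced.  Defaults
        to the whole lower chamber, matching the experimental protocol of
        adding DNase to the lower well.
    """

    x_min: float = 0.0
    x_max: float = 1.0
    x_membrane: float = 0.5
    ecm_interval: tuple[float, float] = (0.35, 0.65)
    injection_interval: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.x_min < self.x_membrane < self.x_max:
            raise ConfigurationError(
                f"x_membrane={self.x_membrane} must lie strictly inside "
                f"({self.x_min}, {self.x_max})"
            )
        a, b = self.ecm_interval
        if not (self.x_min <= a < self.x_membrane < b <= self.x_max):
            raise ConfigurationError(
                f"ecm_interval={self.ecm_interval} must lie inside the domain and "
                "contain the membrane in its interior"
            )
        if self.injection_interval is None:
            object.__setattr__(self, "injection_interval", (self.x_min, self.x_membrane))
        ia, ib = self.injection_interval
        if not (self.x_min <= ia <= ib <= self.x_max):
            raise ConfigurationError(
                f"injection_interval={self.injection_interval} must lie inside the domain"
            )

    @property
    def lower_interval(self) -> tuple[float, float]:
        return (self.x_min, self.x_membrane)

    @property
    def upper_interval(self) -> tuple[float, float]:
        return (self.x_membrane, self.x_max)


@dataclass(frozen=True)
class Grid:
    """Uniform cell-centered finite-volume mesh."""

    h: float
    cell_centers: np.ndarray = field(repr=False)
    face_coordinates: np.ndarray = field(repr=False)
    membrane_face_index: int
    geometry: Geometry

    @property
    def n_cells(self) -> int:
        return self.cell_centers.size

    def lower_mask(self) -> np.ndarray:
        """Indicator of lower-chamber cells (center below the membrane)."""
        return region_mask(self, self.geometry.lower_interval)

    def upper_mask(self) -> np.ndarray:
        return region_mask(self, self.geometry.upper_interval)

    def ecm_mask(self) -> np.ndarray:
        return region_mask(self, self.geometry.ecm_interval)

    def injection_mask(self) -> np.ndarray:
        return region_mask(self, self.geometry.injection_interval)


def _near_integer(x: float, tol: float = 1e-9) -> bool:
    return abs(x - round(x)) < tol


def build_grid(geometry: Geometry, h: float = 0.01) -> Grid:
    """Build the uniform mesh, requiring the membrane to sit on a face.

    Raises
    ------
    ConfigurationError
        If ``(x_max - x_min)/h`` or ``(x_membrane - x_min)/h`` is not an
        integer (the membrane must coincide exactly with a face).
    """
    if h <= 0:
        raise ConfigurationError(f"grid spacing h={h} must be positive")
    span = geometry.x_max - geometry.x_min
    if not _near_integer(span / h):
        raise ConfigurationError(
            f"domain length {span} is not an integer multiple of h={h}"
        )
    mem_off = geometry.x_membrane - geometry.x_min
    if not _near_integer(mem_off / h):
        raise ConfigurationError(
            f"membrane offset {mem_off} is not an integer multiple of h={h}; "
            "the membrane must coincide with a cell face"
        )
    n_cells = round(span / h)
    faces = geometry.x_min + h * np.arange(n_cells + 1)
    centers = 0.5 * (faces[:-1] + faces[1:])
    return Grid(
        h=h,
        cell_centers=centers,
        face_coordinates=faces,
        membrane_face_index=round(mem_off / h),
        geometry=geometry,
    )


def region_mask(grid: Grid, interval: tuple[float, float]) -> np.ndarray:
    """Per-cell indicator of an interval (cell-center membership, [a, b)).

    The half-open convention applies at interior shared boundaries; the
    domain's upper end is treated as closed so a full-domain interval
    flags every cell.  Cell centers never coincide with faces on a
    uniform mesh, so in practice either convention yields the same mask
    for face-aligned intervals.
    """
    a, b = interval
    x = grid.cell_centers
    if b >= grid.geometry.x_max:
        sel = (x >= a) & (x <= b)
    else:
        sel = (x >= a) & (x < b)
    return sel.astype(float)
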