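"""Initiator-row initial conditions and idealized synthetic spot fields.

The embryo's dorsolateral row of enlarged denticle placodes is modelled as a
row of activator discs seeded at concentration u0 on a zero background, with
the inhibitor zero everywhere:

    u(0, x, y) = u0  where (x - x_i)^2 + (y - y_i)^2 < R_spot^2 for some i
    v(0, x, y) = 0.

Three geometries are provided: the catshark six-spot row, the same row with
one spot ablated (the in-silico analogue of the bead-inhibition gap
experiment), and the skate three-spot row of fewer, larger, more widely
spaced spots.  ``synthetic_spot_field`` builds idealized disc fields with
the same rasterization rule so the pattern-analysis stage is testable
without running the solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid_solver import GridSpec

__all__ = ["SpotConfig", "build_initial_condition", "catshark_config",
           "gap_config", "skate_config", "synthetic_spot_field"]


@dataclass(frozen=True)
class SpotConfig:
    """Initiator-row geometry: spot count, radius, centers, seed level.

    ``removed_indices`` lists spots omitted from seeding (gap-ablation
    experiments); the centers stay in the list so analysis code can ask
    where the removed spot would have been.
    """

    n_spot: int
    R_spot: float
    centers: tuple[tuple[float, float], ...]
    u0: float = 5.0
    removed_indices: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "centers",
                           tuple((float(x), float(y)) for x, y in self.centers))
        object.__setattr__(self, "removed_indices",
                           frozenset(self.removed_indices))
        if len(self.centers) != self.n_spot:
            raise ValueError("len(centers) must equal n_spot")
        if not (self.R_spot > 0 and self.u0 > 0):
            raise ValueError("R_spot and u0 must be positive")
        if not self.removed_indices <= set(range(self.n_spot)):
            raise ValueError("removed_indices out of range")

    @property
    def active_centers(self) -> list[tuple[float, float]]:
        return [c for i, c in enumerate(self.centers)
                if i not in self.removed_indices]

    @property
    def removed_centers(self) -> list[tuple[float, float]]:
        return [self.centers[i] for i in sorted(self.removed_indices)]

    def to_dict(self) -> dict:
        return {"n_spot": self.n_spot, "R_spot": self.R_spot,
                "centers": [list(c) for c in self.centers], "u0": self.u0,
                "removed_indices": sorted(self.removed_indices)}

    @classmethod
    def from_dict(cls, d: dict) -> "SpotConfig":
        return cls(n_spot=int(d["n_spot"]), R_spot=float(d["R_spot"]),
                   centers=tuple(tuple(c) for c in d["centers"]),
                   u0=float(d.get("u0", 5.0)),
                   removed_indices=frozenset(d.get("removed_indices", ())))

    def replace(self, **changes) -> "SpotConfig":
        d = self.to_dict()
        d.update(changes)
        return SpotConfig.from_dict(d)


def _disc_mask(centers, radius: float, g: GridSpec) -> np.ndarray:
    """Union of discs rasterized on cell centers with the strict inequality.

    A cell belongs to a disc iff its center ((i+0.5)dx, (j+0.5)dx) satisfies
    (x - x_c)^2 + (y - y_c)^2 < radius^2 (ties excluded).  Shared by
    `build_initial_condition` and `synthetic_spot_field` so both rasterize
    identically.
    """
    coords = (np.arange(g.n) + 0.5) * g.dx
    X, Y = np.meshgrid(coords, coords)  # X varies along columns, Y along rows
    mask = np.zeros((g.n, g.n), dtype=bool)
    r2 = radius * radius
    for xc, yc in centers:
        mask |= (X - xc) ** 2 + (Y - yc) ** 2 < r2
    return mask


def build_initial_condition(cfg: SpotConfig,
                            g: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Seed u = u0 inside every non-removed initiator disc; v = 0 everywhere.

    Overlapping discs still seed u0 (union, not sum).  Discs centered on the
    domain boundary are clipped to half-discs; there is no periodic image.
    """
    mask = _disc_mask(cfg.active_centers, cfg.R_spot, g)
    u = np.where(mask, cfg.u0, 0.0)
    v = np.zeros((g.n, g.n))
    return u, v


def catshark_config(L: float = 75.0, u0: float = 5.0) -> SpotConfig:
    """Six spots of radius 4.5 at (i L/5, L/2), i = 0..5.

    The first and last centers sit on the domain boundary (half-spots).
    """
    centers = tuple((i * L / 5.0, L / 2.0) for i in range(6))
    return SpotConfig(n_spot=6, R_spot=4.5, centers=centers, u0=u0)


def gap_config(L: float = 75.0, u0: float = 5.0) -> SpotConfig:
    """The catshark row with the third spot (center (2L/5, L/2)) ablated."""
    cfg = catshark_config(L=L, u0=u0)
    return cfg.replace(removed_indices=[2])


def skate_config(L: float = 75.0, u0: float = 5.0) -> SpotConfig:
    """Three spots of radius 5.25 at ((3i+2) L/10, L/2): fewer, larger,
    more widely spaced than the catshark row."""
    centers = tuple(((3 * i + 2) * L / 10.0, L / 2.0) for i in range(3))
    return SpotConfig(n_spot=3, R_spot=5.25, centers=centers, u0=u0)


def synthetic_spot_field(spot_centers, radius: float, value: float,
                         g: GridSpec) -> np.ndarray:
    """Idealized field of discs at ``value`` on a zero background.

    Fixture generator for exercising the analysis stage on fields with known
    geometry; uses the same cell-center rasterization as
    `build_initial_condition`.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    return np.where(_disc_mask(spot_centers, radius, g), float(value), 0.0)
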