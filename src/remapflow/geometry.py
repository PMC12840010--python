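"""Arena geometry: a regular octagon with one reward/cue port per wall.

Conventions used throughout the package:

* the arena is a regular octagon of circumradius ``radius`` (default 20 cm)
  centred on the origin;
* walls are indexed 0..7 counter-clockwise starting at East, so wall ``k``
  has its outward normal at angle ``k * 45°`` (0=E, 1=NE, 2=N, 3=NW, 4=W,
  5=SW, 6=S, 7=SE);
* each wall carries a port at its midpoint, i.e. at distance
  ``radius * cos(pi/8)`` (the apothem) from the centre along the wall normal;
* directional analyses use 45°-wide angular bins centred on the wall-normal
  angles, so angular bin ``k`` "points at" wall ``k``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

N_WALLS = 8
WALL_STEP = 2.0 * np.pi / N_WALLS

WALL_NAMES = ("E", "NE", "N", "NW", "W", "SW", "S", "SE")


def wall_angle(wall: int | np.ndarray) -> np.ndarray:
    """Outward-normal angle of a wall, in radians in [-pi, pi)."""
    a = (np.asarray(wall) * WALL_STEP + np.pi) % (2 * np.pi) - np.pi
    return a


def angle_to_wall(theta: np.ndarray) -> np.ndarray:
    """Nearest wall index for an angle in radians (bin edges at +-22.5 deg)."""
    return np.mod(np.round(np.asarray(theta) / WALL_STEP).astype(int), N_WALLS)


@dataclass
class ArenaGeometry:
    """Octagonal arena with per-context light cues and reward ports.

    ``lightcue_walls`` and ``reward_wall`` are keyed by context label
    (``"A"``/``"B"`` for discrimination, ``"C"``/``"D"`` for generalization).
    ``reference_point`` is the reference used for egocentric (relative
    running direction) analyses; it defaults to the arena centre and can be
    set to a port position for landmark-referenced runs.
    """

    radius: float = 20.0
    lightcue_walls: dict = field(default_factory=dict)
    reward_wall: dict = field(default_factory=dict)
    reference_point: tuple = (0.0, 0.0)

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("arena radius must be positive")
        for ctx, walls in self.lightcue_walls.items():
            if any(not (0 <= w < N_WALLS) for w in walls):
                raise ValueError(f"invalid light-cue wall id for context {ctx}")
        for ctx, w in self.reward_wall.items():
            if not (0 <= w < N_WALLS):
                raise ValueError(f"invalid reward wall id for context {ctx}")

    # -- geometry ---------------------------------------------------------

    @property
    def apothem(self) -> float:
        return self.radius * np.cos(np.pi / N_WALLS)

    def port_position(self, wall: int) -> np.ndarray:
        """(x, y) of the port at the midpoint of ``wall``, on the boundary."""
        a = wall_angle(wall)
        return self.apothem * np.array([np.cos(a), np.sin(a)])

    def port_positions(self) -> np.ndarray:
        """(8, 2) array of all port positions."""
        return np.stack([self.port_position(w) for w in range(N_WALLS)])

    def contains(self, xy: np.ndarray, margin: float = 0.0) -> np.ndarray:
        """Boolean point-in-octagon test (vectorised over rows of ``xy``)."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        angles = wall_angle(np.arange(N_WALLS))
        normals = np.stack([np.cos(angles), np.sin(angles)], axis=1)  # (8, 2)
        proj = xy @ normals.T
        return np.all(proj <= self.apothem - margin, axis=1)

    def reward_positions(self) -> dict:
        return {ctx: self.port_position(w) for ctx, w in self.reward_wall.items()}

    @property
    def contexts(self) -> list:
        return sorted(self.reward_wall)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lightcue_walls"] = {k: sorted(v) for k, v in self.lightcue_walls.items()}
        d["reference_point"] = list(self.reference_point)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ArenaGeometry":
        return cls(
            radius=d["radius"],
            lightcue_walls={k: set(v) for k, v in d["lightcue_walls"].items()},
            reward_wall={k: int(v) for k, v in d["reward_wall"].items()},
            reference_point=tuple(d["reference_point"]),
        )


def default_geometry(paradigm: str = "discrimination", radius: float = 20.0) -> ArenaGeometry:
    """Standard two-context task geometries.

    Discrimination: context A is cued at E-NE and rewarded at the W port;
    context B is cued at the adjacent N-NW walls and rewarded at the E port.
    Generalization: contexts C (W-SW cues) and D (S-SE cues) share a single
    reward port at the N wall.
    """
    if paradigm == "discrimination":
        return ArenaGeometry(
            radius=radius,
            lightcue_walls={"A": {0, 1}, "B": {2, 3}},
            reward_wall={"A": 4, "B": 0},
        )
    if paradigm == "generalization":
        return ArenaGeometry(
            radius=radius,
            lightcue_walls={"C": {4, 5}, "D": {6, 7}},
            reward_wall={"C": 2, "D": 2},
        )
    raise ValueError(f"unknown paradigm: {paradigm!r}")
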