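"""Virtual underwater arenas and their geometry.

The task environment is a square, depth-constrained arena (default
4 m x 4 m, coordinates in [-2, 2]^2) scattered with circular obstacles
("corals") of fixed radius. The agent starts in one quadrant and must
reach a food target stochastically placed in the opposite quadrant.

Coordinate convention: ``x`` is the horizontal axis (length), ``z`` the
vertical axis (depth, positive up). Headings are measured counter-clockwise
from +x, in radians. Distances along a viewing direction are measured to
the nearest *surface* (coral perimeter or arena wall); collisions are
scored on center distance < coral radius, so the agent is a point that may
graze obstacle surfaces without colliding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "ArenaConfig",
    "Environment",
    "PlacementError",
    "generate_environment",
    "coral_aperture",
    "distance_along_direction",
    "affected_bins",
    "check_collision",
]

CLEAR = np.inf
"""Sentinel returned by ray queries when no boundary lies within range."""


class PlacementError(RuntimeError):
    """Raised when corals/start/target cannot be placed in the arena."""


@dataclass(frozen=True)
class ArenaConfig:
    """Geometry and task constants of one arena.

    Parameters
    ----------
    width, height:
        Horizontal length and vertical extent in meters. The arena spans
        ``[-width/2, width/2] x [-height/2, height/2]``.
    n_corals:
        Number of circular obstacles.
    coral_radius:
        Obstacle radius in meters.
    v_max:
        Maximal swimming speed in m/s.
    t_max:
        Trial duration cap in seconds.
    walls_are_boundaries:
        Whether arena walls are visible to ray casts (boundary cells
        respond to walls, and the agent must not leave the arena).
    """

    width: float = 4.0
    height: float = 4.0
    n_corals: int = 25
    coral_radius: float = 0.15
    v_max: float = 0.5
    t_max: float = 45.0
    walls_are_boundaries: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("arena dimensions must be positive")
        if self.n_corals < 0:
            raise ValueError("n_corals must be >= 0")
        if self.coral_radius <= 0:
            raise ValueError("coral_radius must be positive")
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, zmin, zmax)."""
        return (-self.width / 2, self.width / 2, -self.height / 2, self.height / 2)


@dataclass
class Environment:
    """One concrete arena: obstacle layout plus start/target placement."""

    config: ArenaConfig
    coral_centers: np.ndarray  # (n, 2)
    start: np.ndarray  # (2,)
    target: np.ndarray  # (2,)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.coral_centers = np.atleast_2d(np.asarray(self.coral_centers, dtype=float))
        if self.coral_centers.size == 0:
            self.coral_centers = np.empty((0, 2))
        self.start = np.asarray(self.start, dtype=float)
        self.target = np.asarray(self.target, dtype=float)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return self.config.bounds

    @property
    def straight_distance(self) -> float:
        """Euclidean start-to-target distance in meters."""
        return float(np.linalg.norm(self.target - self.start))

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "config": asdict(self.config),
            "coral_centers": self.coral_centers.tolist(),
            "start": self.start.tolist(),
            "target": self.target.tolist(),
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "Environment":
        p = Path(source)
        payload = json.loads(p.read_text() if p.exists() else str(source))
        return cls(
            config=ArenaConfig(**payload["config"]),
            coral_centers=np.asarray(payload["coral_centers"], dtype=float),
            start=np.asarray(payload["start"]),
            target=np.asarray(payload["target"]),
            seed=payload.get("seed"),
        )


_QUADRANT_SIGNS = np.array([[1, 1], [-1, 1], [-1, -1], [1, -1]], dtype=float)


def _sample_in_quadrant(
    rng: np.random.Generator, quadrant: int, half: np.ndarray, margin: float
) -> np.ndarray:
    lo = np.full(2, margin)
    pt = rng.uniform(lo, half - margin)
    return pt * _QUADRANT_SIGNS[quadrant]


def generate_environment(
    config: ArenaConfig,
    seed: int | None = None,
    *,
    start: np.ndarray | None = None,
    target: np.ndarray | None = None,
    clearance: float = 0.1,
    max_retries: int = 1000,
) -> Environment:
    """Generate a seeded arena with start/target in opposite quadrants.

    Corals are placed uniformly inside the bounds, rejection-sampled so no
    coral disk (plus ``clearance``) covers the start or target. When
    ``start``/``target`` are given (e.g. the planner baseline's fixed
    corners) they are used verbatim; otherwise both are sampled uniformly
    within two randomly chosen opposite quadrants, outside all coral disks.

    Deterministic under a fixed ``(config, seed)`` pair.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    half = np.array([config.width / 2, config.height / 2])
    r = config.coral_radius

    if start is None or target is None:
        q = int(rng.integers(4))
        # opposite quadrant is diagonally across
        margin = min(0.05 * float(half.min()), 0.1)
        start = _sample_in_quadrant(rng, q, half, margin)
        target = _sample_in_quadrant(rng, (q + 2) % 4, half, margin)
    start = np.asarray(start, dtype=float)
    target = np.asarray(target, dtype=float)

    centers = np.empty((0, 2))
    if config.n_corals > 0:
        keep_out = np.stack([start, target])
        placed: list[np.ndarray] = []
        attempts = 0
        while len(placed) < config.n_corals:
            attempts += 1
            if attempts > max_retries * max(config.n_corals, 1):
                raise PlacementError(
                    f"could not place {config.n_corals} corals after "
                    f"{attempts} attempts"
                )
            c = rng.uniform(-half, half)
            if np.min(np.linalg.norm(keep_out - c, axis=1)) <= r + clearance:
                continue
            placed.append(c)
        centers = np.stack(placed)

    return Environment(
        config=config, coral_centers=centers, start=start, target=target, seed=seed
    )


def coral_aperture(d: float | np.ndarray, r: float) -> float | np.ndarray:
    """Angular extent 2*arctan(r/d) a coral of radius ``r`` subtends at
    center distance ``d`` (both in meters; result in radians)."""
    if np.any(np.asarray(d) <= 0):
        raise ValueError("distance to coral center must be positive")
    if r <= 0:
        raise ValueError("coral radius must be positive")
    return 2.0 * np.arctan(r / np.asarray(d))


def _ray_circle_distance(
    pos: np.ndarray, u: np.ndarray, centers: np.ndarray, r: float
) -> np.ndarray:
    """Distance from ``pos`` along unit direction ``u`` to each circle's
    near surface; inf where the ray misses. Vectorised over centers."""
    if centers.size == 0:
        return np.empty(0)
    delta = centers - pos  # (n, 2)
    t_ca = delta @ u  # closest-approach parameter
    d2 = np.einsum("ij,ij->i", delta, delta) - t_ca**2
    disc = r * r - d2
    hit = disc >= 0
    out = np.full(len(centers), np.inf)
    root = np.sqrt(np.where(hit, disc, 0.0))
    t0 = t_ca - root
    t1 = t_ca + root
    # entering intersection if ahead; if pos is inside the disk, distance 0
    t = np.where(t0 >= 0, t0, np.where(t1 >= 0, 0.0, np.inf))
    out[hit] = t[hit]
    return out


def _ray_wall_distance(
    pos: np.ndarray, u: np.ndarray, bounds: tuple[float, float, float, float]
) -> float:
    """Distance along ``u`` to the arena walls (inf if moving away, which
    cannot happen from inside the bounds)."""
    xmin, xmax, zmin, zmax = bounds
    best = np.inf
    for axis, (lo, hi) in enumerate(((xmin, xmax), (zmin, zmax))):
        if u[axis] > 1e-12:
            best = min(best, (hi - pos[axis]) / u[axis])
        elif u[axis] < -1e-12:
            best = min(best, (lo - pos[axis]) / u[axis])
    return max(best, 0.0)


def distance_along_direction(
    env: Environment,
    pos: np.ndarray,
    angle: float,
    max_range: float = 1.4,
) -> float:
    """Distance from ``pos`` to the nearest boundary surface along a ray.

    Returns ``CLEAR`` (``inf``) when no coral surface or wall lies within
    ``max_range``. Walls count as boundaries when the arena config says so.
    """
    if max_range <= 0:
        raise ValueError("max_range must be positive")
    pos = np.asarray(pos, dtype=float)
    u = np.array([np.cos(angle), np.sin(angle)])
    d = np.inf
    hits = _ray_circle_distance(pos, u, env.coral_centers, env.config.coral_radius)
    if hits.size:
        d = float(np.min(hits))
    if env.config.walls_are_boundaries:
        d = min(d, _ray_wall_distance(pos, u, env.bounds))
    return d if d <= max_range else CLEAR


def wrap_angle(theta: float | np.ndarray) -> float | np.ndarray:
    """Wrap angle(s) to (-pi, pi]."""
    out = np.mod(np.asarray(theta) + np.pi, 2 * np.pi) - np.pi
    out = np.where(out == -np.pi, np.pi, out)
    return float(out) if np.isscalar(theta) else out


def bin_directions(n_bins: int, heading: float = 0.0) -> np.ndarray:
    """Allocentric center directions of the egocentric angular bins.

    Bin 0 points straight ahead; bins advance counter-clockwise in steps of
    ``2*pi/n_bins``, so for 24 bins bin 1 is 15 deg to the left and bin 23
    is 15 deg to the right.
    """
    return heading + np.arange(n_bins) * (2 * np.pi / n_bins)


def affected_bins(
    env: Environment,
    pos: np.ndarray,
    coral: np.ndarray,
    n_bins: int = 24,
    max_range: float = 1.4,
    heading: float = 0.0,
) -> dict[int, float]:
    """Angular bins onto which one coral projects, with per-bin distances.

    A bin is affected when its center direction falls within the coral's
    aperture around the coral's bearing; the paired value is the surface
    distance along that bin's direction. Empty when the coral's near
    surface lies beyond ``max_range``.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    pos = np.asarray(pos, dtype=float)
    coral = np.asarray(coral, dtype=float)
    r = env.config.coral_radius
    delta = coral - pos
    d = float(np.linalg.norm(delta))
    if d - r > max_range or d == 0.0:
        return {}
    bearing = np.arctan2(delta[1], delta[0])
    half_ap = coral_aperture(d, r) / 2.0
    dirs = bin_directions(n_bins, heading)
    rel = wrap_angle(dirs - bearing)
    out: dict[int, float] = {}
    for i in np.nonzero(np.abs(rel) <= half_ap)[0]:
        u = np.array([np.cos(dirs[i]), np.sin(dirs[i])])
        di = _ray_circle_distance(pos, u, coral[None, :], r)[0]
        if not np.isfinite(di):  # tangent-ray rounding
            di = max(d - r, 0.0)
        if di <= max_range:
            out[int(i)] = float(di)
    return out


def check_collision(env: Environment, pos: np.ndarray) -> bool:
    """True iff ``pos`` lies strictly within any coral disk (center
    distance < radius)."""
    if env.coral_centers.size == 0:
        return False
    d = np.linalg.norm(env.coral_centers - np.asarray(pos, dtype=float), axis=1)
    return bool(np.min(d) < env.config.coral_radius)
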