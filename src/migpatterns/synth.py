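"""Seeded synthetic population generators.

Two regimes are emulated: populations spread isotropically over the whole
globe, and populations clustered inside a small spherical cap — the regime
of a real archipelago-scale study system, where the Delaunay cells on the
far side of the sphere become very large.  All randomness flows through a
single seeded generator so every draw is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geo import GeoPopulation

_MAX_LAT = 89.999  # stay off the poles, which the geometry rejects


@dataclass(frozen=True)
class SyntheticConfig:
    n: int
    mode: str = "uniform"            # "uniform" | "cap"
    cap_center: tuple[float, float] = (120.0, -9.5)   # lon, lat degrees
    cap_radius_deg: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n < 4:
            raise ValueError("need n >= 4 populations")
        if self.mode not in ("uniform", "cap"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "cap" and not self.cap_radius_deg > 0:
            raise ValueError("cap_radius_deg must be positive")


def _to_population(i: int, x: np.ndarray) -> GeoPopulation:
    lat = float(np.degrees(np.arcsin(np.clip(x[2], -1.0, 1.0))))
    lat = float(np.clip(lat, -_MAX_LAT, _MAX_LAT))
    lon = float(np.degrees(np.arctan2(x[1], x[0])))
    return GeoPopulation(f"P{i:03d}", lon, lat)


def random_points(config: SyntheticConfig) -> list[GeoPopulation]:
    """Draw ``n`` named points, isotropically or inside a spherical cap."""
    rng = np.random.default_rng(config.seed)
    if config.mode == "uniform":
        x = rng.normal(size=(config.n, 3))
        x /= np.linalg.norm(x, axis=1, keepdims=True)
    else:
        r = np.radians(config.cap_radius_deg)
        # area-uniform in the polar cap, then rotate the pole to the center
        z = 1.0 - rng.random(config.n) * (1.0 - np.cos(r))
        az = rng.random(config.n) * 2.0 * np.pi
        rho = np.sqrt(1.0 - z**2)
        x = np.c_[rho * np.cos(az), rho * np.sin(az), z]
        lon0, lat0 = config.cap_center
        from .geo import latlon_to_unit

        c = latlon_to_unit(lon0, lat0)
        zhat = np.array([0.0, 0.0, 1.0])
        v = np.cross(zhat, c)
        s = np.linalg.norm(v)
        if s < 1e-15:
            rot = np.eye(3) if c[2] > 0 else np.diag([1.0, -1.0, -1.0])
        else:
            vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
            rot = np.eye(3) + vx + vx @ vx * ((1 - zhat @ c) / s**2)
        x = x @ rot.T
    return [_to_population(i, xi) for i, xi in enumerate(x)]
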