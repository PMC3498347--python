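"""Microphone-array geometry, image plane and propagation delays.

The acoustic camera used here is a planar star-shaped array of M
microphones lying in the ``z = 0`` plane, focused on an image plane
parallel to it at ``z = distance`` (x right, y up, all coordinates in
meters).  Delay-and-sum focusing needs, for every focus point ``x``, the
absolute run times ``pi_i = |r_i| / v`` from each microphone to ``x``
and the relative delays ``Delta_i = pi_i - min(pi_i)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ArrayGeometry",
    "PropagationModel",
    "ImagePlane",
    "InvalidGeometryError",
    "DegenerateGeometryError",
    "build_star_array",
    "run_times",
    "relative_delays",
]


class InvalidGeometryError(ValueError):
    """Raised for unusable array specifications (bad span, counts, weights)."""


class DegenerateGeometryError(ValueError):
    """Raised when a focus point coincides with a microphone."""


@dataclass(frozen=True)
class PropagationModel:
    """Free-field propagation assumptions.

    speed_of_sound
        Speed of sound in air, m/s.  Default 343.0 (20 degC).  Note that
        the quarter-wave tube model in :mod:`rumblecam.call_acoustics`
        carries its *own* speed of sound (350 m/s); the two are distinct
        configuration values and are never shared implicitly.
    attenuation
        ``"spherical"`` for 1/r amplitude decay, ``"none"`` for pure
        delays (useful in oracle tests).
    """

    speed_of_sound: float = 343.0
    attenuation: str = "spherical"

    def __post_init__(self) -> None:
        if self.speed_of_sound <= 0:
            raise ValueError("speed_of_sound must be positive")
        if self.attenuation not in ("spherical", "none"):
            raise ValueError(f"unknown attenuation model {self.attenuation!r}")


@dataclass(frozen=True)
class ImagePlane:
    """Rectangular focusing grid parallel to the array plane.

    The plane is centred on the array axis at ``z = distance``; pixels
    are uniform cells of size (width/nx, height/ny) addressed by
    (row iy, col ix) with iy increasing upward.
    """

    distance: float = 8.0
    width: float = 4.0
    height: float = 3.0
    nx: int = 64
    ny: int = 48

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("plane distance must be positive")
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid resolution must be at least 1x1")

    @property
    def pixel_size(self) -> tuple[float, float]:
        return self.width / self.nx, self.height / self.ny

    def x_coords(self) -> np.ndarray:
        dx = self.width / self.nx
        return -self.width / 2 + dx * (np.arange(self.nx) + 0.5)

    def y_coords(self) -> np.ndarray:
        dy = self.height / self.ny
        return -self.height / 2 + dy * (np.arange(self.ny) + 0.5)

    def pixel_centers(self) -> np.ndarray:
        """All pixel-centre coordinates, shape (ny, nx, 3)."""
        xs = self.x_coords()
        ys = self.y_coords()
        gx, gy = np.meshgrid(xs, ys)
        pts = np.stack([gx, gy, np.full_like(gx, self.distance)], axis=-1)
        return pts

    def pixel_center(self, iy: int, ix: int) -> np.ndarray:
        return np.array([self.x_coords()[ix], self.y_coords()[iy], self.distance])

    def nearest_pixel(self, point) -> tuple[int, int]:
        """(iy, ix) of the pixel whose centre is nearest to ``point``."""
        p = np.asarray(point, dtype=float)
        ix = int(np.argmin(np.abs(self.x_coords() - p[0])))
        iy = int(np.argmin(np.abs(self.y_coords() - p[1])))
        return iy, ix


@dataclass
class ArrayGeometry:
    """Microphone positions (M, 3) and non-negative shading weights (M,)."""

    mic_positions: np.ndarray
    weights: np.ndarray = None  # type: ignore[assignment]
    name: str = ""

    def __post_init__(self) -> None:
        self.mic_positions = np.atleast_2d(np.asarray(self.mic_positions, dtype=float))
        if self.mic_positions.ndim != 2 or self.mic_positions.shape[1] != 3:
            raise InvalidGeometryError("mic_positions must have shape (M, 3)")
        if self.mic_positions.shape[0] < 1:
            raise InvalidGeometryError("need at least one microphone")
        if self.weights is None:
            self.weights = np.ones(self.n_mics)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.n_mics,):
            raise InvalidGeometryError("weights must have shape (M,)")
        if np.any(self.weights < 0) or not np.any(self.weights > 0):
            raise InvalidGeometryError(
                "weights must be non-negative with at least one positive entry"
            )

    @property
    def n_mics(self) -> int:
        return self.mic_positions.shape[0]

    def max_span(self) -> float:
        """Maximum pairwise microphone distance (the array's span width)."""
        d = self.mic_positions[:, None, :] - self.mic_positions[None, :, :]
        return float(np.sqrt((d**2).sum(axis=-1)).max())

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "mic_positions": self.mic_positions.tolist(),
            "weights": self.weights.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArrayGeometry":
        return cls(
            mic_positions=np.asarray(d["mic_positions"], dtype=float),
            weights=np.asarray(d["weights"], dtype=float),
            name=d.get("name", ""),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path) -> "ArrayGeometry":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_star_array(
    n_arms: int = 3, mics_per_arm: int = 16, span: float = 3.4, name: str = ""
) -> ArrayGeometry:
    """Equiangular star array in the z = 0 plane.

    ``n_arms`` straight arms with ``mics_per_arm`` microphones each,
    logarithmically spaced along the arm, scaled so the maximum pairwise
    microphone distance equals ``span`` exactly, then recentred so the
    centroid sits at the origin.  Unit shading weights.

    The defaults (3 x 16, 3.4 m) match the span width and channel count
    of the commercial 48-channel star array; the exact radial layout of
    that instrument is unpublished, so results that depend on the
    microphone placement beyond span and count are layout-dependent.
    """
    if n_arms < 1 or mics_per_arm < 1:
        raise InvalidGeometryError("n_arms and mics_per_arm must be >= 1")
    if span <= 0:
        raise InvalidGeometryError("span must be positive")

    if n_arms * mics_per_arm == 1:
        return ArrayGeometry(np.zeros((1, 3)), name=name or "single-mic")

    # log spacing from a quarter of the tip radius outward: keeps some
    # mics near the centre (sidelobe control) without collapsing the
    # effective aperture, which sets the map's low-frequency contrast
    if mics_per_arm == 1:
        radii = np.array([1.0])
    else:
        r_min = 1.0 / 4.0
        radii = r_min * (1.0 / r_min) ** (np.arange(mics_per_arm) / (mics_per_arm - 1))
    angles = 2 * np.pi * np.arange(n_arms) / n_arms
    pos = np.array(
        [[r * np.cos(a), r * np.sin(a), 0.0] for a in angles for r in radii]
    )
    d = pos[:, None, :] - pos[None, :, :]
    max_d = np.sqrt((d**2).sum(axis=-1)).max()
    if max_d == 0:  # all mics coincide (n_arms >= 2 never hits this)
        raise InvalidGeometryError("degenerate layout: all microphones coincide")
    pos *= span / max_d
    pos -= pos.mean(axis=0)
    return ArrayGeometry(pos, name=name or f"star-{n_arms * mics_per_arm}")


def run_times(
    geometry: ArrayGeometry, point, model: PropagationModel
) -> np.ndarray:
    """Absolute travel times ``pi_i = |r_i| / v`` from each mic to ``point``."""
    p = np.asarray(point, dtype=float)
    r = np.linalg.norm(geometry.mic_positions - p[None, :], axis=1)
    if np.any(r < 1e-12):
        raise DegenerateGeometryError("focus point coincides with a microphone")
    return r / model.speed_of_sound


def relative_delays(times) -> np.ndarray:
    """``Delta_i = pi_i - min(pi_i)``; the minimum entry is exactly zero."""
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("empty run-time list")
    return t - t.min()
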