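"""Sensor geometries: scalp electrodes on a sphere and SEEG depth shafts.

Scalp sensors are placed quasi-uniformly on the upper hemisphere of the
spherical head model (Fibonacci spiral).  Depth electrodes are straight shafts
of equally spaced contacts (3.5 mm center-to-center), numbered from 1 at the
deepest contact, following clinical convention.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np

__all__ = ["Sensor", "SensorGeometry", "GeometryError", "make_geometry",
           "CONTACT_SPACING_MM", "label_contacts_by_proximity"]

CONTACT_SPACING_MM = 3.5


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class Sensor:
    id: str
    modality: str                  # "scalp" | "depth"
    position_mm: tuple[float, float, float]
    shaft_id: str | None = None
    contact_index: int | None = None


@dataclass
class SensorGeometry:
    sensors: list[Sensor]
    sphere_radius_mm: float

    def __post_init__(self) -> None:
        ids = [s.id for s in self.sensors]
        if len(set(ids)) != len(ids):
            raise GeometryError("sensor ids must be unique")
        r = self.sphere_radius_mm
        for s in self.sensors:
            if s.modality == "scalp":
                if abs(np.linalg.norm(s.position_mm) - r) > 0.1:
                    raise GeometryError(f"scalp sensor {s.id} off the sphere surface")
            elif s.modality != "depth":
                raise GeometryError(f"bad modality {s.modality!r}")
        for shaft, contacts in self.shafts().items():
            pos = np.array([c.position_mm for c in contacts])
            gaps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
            if not np.allclose(gaps, CONTACT_SPACING_MM, atol=1e-6):
                raise GeometryError(f"shaft {shaft} contacts not {CONTACT_SPACING_MM} mm apart")

    def subset(self, modality: str) -> list[Sensor]:
        return [s for s in self.sensors if s.modality == modality]

    @property
    def scalp(self) -> list[Sensor]:
        return self.subset("scalp")

    @property
    def depth(self) -> list[Sensor]:
        return self.subset("depth")

    def shafts(self) -> dict[str, list[Sensor]]:
        out: dict[str, list[Sensor]] = {}
        for s in self.depth:
            out.setdefault(s.shaft_id, []).append(s)
        for shaft in out:
            out[shaft].sort(key=lambda c: c.contact_index)
        return out

    def positions(self, modality: str) -> np.ndarray:
        return np.array([s.position_mm for s in self.subset(modality)], dtype=float)

    def ids(self, modality: str) -> list[str]:
        return [s.id for s in self.subset(modality)]


def _fibonacci_upper_hemisphere(n: int, radius: float) -> np.ndarray:
    """Quasi-uniform points on the upper (z > 0) hemisphere."""
    i = np.arange(n)
    z = (i + 0.5) / n            # uniform in area over the hemisphere
    rho = np.sqrt(1.0 - z ** 2)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i
    pts = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    return radius * pts


def _shaft_names(n: int) -> list[str]:
    letters = string.ascii_uppercase
    names = list(letters) + [a + b for a in letters for b in letters]
    return names[:n]


def make_geometry(
    n_scalp: int = 32,
    n_shafts: int = 10,
    contacts_per_shaft: int = 12,
    sphere_radius_mm: float = 90.0,
    seed: int = 0,
) -> SensorGeometry:
    """Build a scalp montage plus randomly oriented depth shafts.

    Each shaft enters near the sphere surface and aims at a random interior
    target; contacts are numbered 1 (deepest) to ``contacts_per_shaft``
    (shallowest) at 3.5 mm center-to-center spacing.  All contacts are kept at
    least 2 mm inside the head sphere.
    """
    if min(n_scalp, n_shafts, contacts_per_shaft) < 1:
        raise ValueError("all sensor counts must be positive")
    R = float(sphere_radius_mm)
    margin = 2.0
    shaft_len = (contacts_per_shaft - 1) * CONTACT_SPACING_MM
    if shaft_len >= 2 * (R - margin):
        raise GeometryError("shaft longer than the head sphere diameter")

    rng = np.random.default_rng(seed)
    sensors: list[Sensor] = []
    for i, p in enumerate(_fibonacci_upper_hemisphere(n_scalp, R)):
        sensors.append(Sensor(f"EEG{i + 1:03d}", "scalp", tuple(p)))

    for shaft in _shaft_names(n_shafts):
        for _ in range(1000):
            # entry point on the upper half of the sphere, aiming inward
            u = rng.normal(size=3)
            u[2] = abs(u[2])
            entry = (R - margin) * u / np.linalg.norm(u)
            target = rng.uniform(-0.25 * R, 0.25 * R, size=3)
            direction = target - entry
            direction /= np.linalg.norm(direction)
            depth_extent = np.linalg.norm(target - entry)
            tip = entry + direction * depth_extent  # deepest contact at target
            pos = tip[None, :] - np.arange(contacts_per_shaft)[:, None] * \
                CONTACT_SPACING_MM * direction[None, :]
            if np.all(np.linalg.norm(pos, axis=1) < R - margin):
                break
        else:  # pragma: no cover
            raise GeometryError("could not place shaft inside the sphere")
        for k in range(contacts_per_shaft):
            sensors.append(Sensor(f"{shaft}{k + 1:02d}", "depth", tuple(pos[k]),
                                  shaft_id=shaft, contact_index=k + 1))
    return SensorGeometry(sensors, R)


def label_contacts_by_proximity(
    channel_positions_mm: dict[str, np.ndarray],
    region_centers_mm: dict[str, np.ndarray],
    radius_mm: float = 15.0,
) -> dict[str, str]:
    """Assign each channel the label of the nearest region center within radius.

    Channels farther than ``radius_mm`` from every center stay unlabeled
    (absent from the returned mapping) — mirroring that not every contact
    lies in a labeled structure.
    """
    out: dict[str, str] = {}
    for ch, pos in channel_positions_mm.items():
        best, best_d = None, np.inf
        for label, center in region_centers_mm.items():
            d = float(np.linalg.norm(np.asarray(pos) - np.asarray(center)))
            if d < best_d:
                best, best_d = label, d
        if best is not None and best_d <= radius_mm:
            out[ch] = best
    return out
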