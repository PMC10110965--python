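"""Analytic forward models: current dipoles to sensor potentials.

Two conductor models are used, one per modality:

* **Scalp**: a single homogeneous conducting sphere with insulating exterior.
  The surface potential of a current dipole is obtained from the Legendre
  expansion of the infinite-medium potential plus the interior harmonic
  correction enforcing the Neumann boundary condition dV/dr = 0 at the surface.
  For a dipole at eccentricity f = b/R with radial moment p_r and tangential
  moment p_t (observation angle gamma from the dipole axis):

      V = K/R^2 * [ p_r * sum_n (2n+1) f^(n-1) P_n(cos g)
                    + p_t * cos(phi) * sum_n (2n+1)/n f^(n-1) sin(g) P_n'(cos g) ]

  with K = 1e3 / (4 pi sigma) in microvolt per nA*m with distances in mm.

* **Depth**: contacts are embedded in the volume, modeled as an infinite
  homogeneous medium: V = K * p . d / |d|^3, d the source-to-contact vector.

Both gains are linear in the dipole moment; units are microvolt per nA*m.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import SensorGeometry

__all__ = ["HeadModel", "Waveform", "DipoleSource", "DipoleSourceSet",
           "LeadField", "lead_field", "sphere_dipole_potential",
           "infinite_medium_potential"]

_N_TERMS = 300          # Legendre terms; (2n+1) f^(n-1) < 1e-12 at f<=0.93
_MAX_ECCENTRICITY = 0.95


class ForwardModelError(ValueError):
    pass


@dataclass(frozen=True)
class HeadModel:
    """Spherical homogeneous head model."""

    sphere_radius_mm: float = 90.0
    conductivity_S_per_m: float = 0.33
    min_source_sensor_distance_mm: float = 3.0


@dataclass(frozen=True)
class Waveform:
    """Hann (raised-cosine) pulse compactly supported on [t_start, t_stop].

    ``amplitude_nAm`` is the peak dipole moment.
    """

    amplitude_nAm: float
    t_start_s: float
    t_stop_s: float

    def sample(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        width = self.t_stop_s - self.t_start_s
        if width <= 0:
            raise ValueError("waveform window must have positive width")
        inside = (t >= self.t_start_s) & (t <= self.t_stop_s)
        x = (t[inside] - self.t_start_s) / width
        out[inside] = self.amplitude_nAm * np.sin(np.pi * x) ** 2
        return out


@dataclass(frozen=True)
class DipoleSource:
    """One equivalent current dipole with condition-independent and
    condition-differential (OLD minus NEW) components."""

    position_mm: tuple[float, float, float]
    orientation: tuple[float, float, float]
    baseline: Waveform
    differential: Waveform

    def __post_init__(self) -> None:
        n = np.linalg.norm(self.orientation)
        if abs(n - 1.0) > 1e-9:
            raise ValueError("orientation must be unit-norm")

    @property
    def effect_window_s(self) -> tuple[float, float]:
        return (self.differential.t_start_s, self.differential.t_stop_s)


@dataclass
class DipoleSourceSet:
    sources: list[DipoleSource]

    def __post_init__(self) -> None:
        if not self.sources:
            raise ValueError("need at least one source")

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position_mm for s in self.sources], dtype=float)

    @property
    def orientations(self) -> np.ndarray:
        return np.array([s.orientation for s in self.sources], dtype=float)

    @property
    def effect_window_s(self) -> tuple[float, float]:
        starts = [s.differential.t_start_s for s in self.sources]
        stops = [s.differential.t_stop_s for s in self.sources]
        return (min(starts), max(stops))


@dataclass
class LeadField:
    """Gain from unit dipoles to sensors, microvolt per nA*m.

    ``gain`` has shape (n_channels, n_sources, 3), one column triplet per
    source for moments along x, y, z.
    """

    gain: np.ndarray
    channel_ids: list[str]
    source_positions_mm: np.ndarray

    def __post_init__(self) -> None:
        if self.gain.ndim != 3 or self.gain.shape[2] != 3:
            raise ValueError("gain must be (channels, sources, 3)")
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("gain contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]

    def matrix(self) -> np.ndarray:
        """Flattened (channels, sources * 3) gain matrix."""
        return self.gain.reshape(self.n_channels, -1)

    def fixed(self, orientations: np.ndarray) -> np.ndarray:
        """(channels, sources) gain for fixed unit orientations."""
        return np.einsum("csk,sk->cs", self.gain, np.asarray(orientations, float))


def _legendre_sums(x: np.ndarray, f: float, n_terms: int = _N_TERMS):
    """S1 = sum (2n+1) f^(n-1) P_n(x);  S2 = sum (2n+1)/n f^(n-1) P'_n(x)."""
    x = np.asarray(x, dtype=float)
    p_prev = np.ones_like(x)        # P_0
    p = x.copy()                    # P_1
    dp_prev = np.zeros_like(x)      # P'_0
    dp = np.ones_like(x)            # P'_1
    s1 = 3.0 * p                    # n = 1 term, f^0 = 1
    s2 = 3.0 * dp
    fpow = 1.0
    for n in range(1, n_terms):
        # advance P_{n+1}, P'_{n+1}
        p_next = ((2 * n + 1) * x * p - n * p_prev) / (n + 1)
        dp_next = dp_prev + (2 * n + 1) * p
        p_prev, p = p, p_next
        dp_prev, dp = dp, dp_next
        fpow *= f
        m = n + 1
        s1 += (2 * m + 1) * fpow * p
        s2 += (2 * m + 1) / m * fpow * dp
        if (2 * m + 1) * fpow < 1e-14:
            break
    return s1, s2


def sphere_dipole_potential(
    electrodes_mm: np.ndarray,
    dipole_pos_mm: np.ndarray,
    model: HeadModel,
) -> np.ndarray:
    """Gain (n_electrodes, 3) at surface electrodes of the homogeneous sphere.

    Columns are the potentials for unit moments (1 nA*m) along x, y, z.
    """
    el = np.atleast_2d(np.asarray(electrodes_mm, dtype=float))
    r0 = np.asarray(dipole_pos_mm, dtype=float)
    R = model.sphere_radius_mm
    b = np.linalg.norm(r0)
    f = b / R
    if f > _MAX_ECCENTRICITY:
        raise ForwardModelError(
            f"dipole eccentricity {f:.3f} too close to the sphere surface")
    zhat = r0 / b if b > 1e-12 else np.array([0.0, 0.0, 1.0])
    rhat = el / np.linalg.norm(el, axis=1, keepdims=True)
    x = np.clip(rhat @ zhat, -1.0, 1.0)
    s1, s2 = _legendre_sums(x, f)
    K = 1e3 / (4.0 * np.pi * model.conductivity_S_per_m)   # uV per nA*m, mm
    # V = K/R^2 [ S1 (p.zhat) + S2 (p.(rhat - x zhat)) ]
    radial = s1[:, None] * zhat[None, :]
    tangential = s2[:, None] * (rhat - x[:, None] * zhat[None, :])
    return K / R ** 2 * (radial + tangential)


def infinite_medium_potential(
    contacts_mm: np.ndarray,
    dipole_pos_mm: np.ndarray,
    model: HeadModel,
) -> np.ndarray:
    """Gain (n_contacts, 3) for a dipole in an infinite homogeneous medium."""
    pts = np.atleast_2d(np.asarray(contacts_mm, dtype=float))
    d = pts - np.asarray(dipole_pos_mm, dtype=float)[None, :]
    dist = np.linalg.norm(d, axis=1)
    clamp = model.min_source_sensor_distance_mm
    if np.any(dist < clamp):
        raise ForwardModelError(
            f"source closer than {clamp} mm to a contact (min {dist.min():.2f} mm)")
    K = 1e3 / (4.0 * np.pi * model.conductivity_S_per_m)
    return K * d / dist[:, None] ** 3


def lead_field(
    geometry: SensorGeometry,
    source_positions_mm: np.ndarray,
    model: HeadModel | None = None,
    modality: str = "scalp",
) -> LeadField:
    """Lead field of all sensors of one modality for the given source positions.

    Scalp sensors use the homogeneous-sphere surface solution; depth contacts
    the infinite-medium solution.  Raises :class:`ForwardModelError` when a
    source lies outside the head or violates the distance clamp.
    """
    model = model or HeadModel()
    pos = np.atleast_2d(np.asarray(source_positions_mm, dtype=float))
    sensors = geometry.positions(modality)
    if sensors.size == 0:
        raise ValueError(f"geometry has no {modality} sensors")
    radii = np.linalg.norm(pos, axis=1)
    if np.any(radii >= model.sphere_radius_mm):
        raise ForwardModelError("source outside the head sphere")
    gain = np.empty((sensors.shape[0], pos.shape[0], 3))
    for j, p in enumerate(pos):
        if modality == "scalp":
            gain[:, j, :] = sphere_dipole_potential(sensors, p, model)
        else:
            gain[:, j, :] = infinite_medium_potential(sensors, p, model)
    return LeadField(gain, geometry.ids(modality), pos)
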