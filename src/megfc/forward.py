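"""Magnetic forward model for dipoles in a spherically symmetric conductor.

The field of a current dipole inside a spherical conductor is evaluated with
the closed-form expression for the external field (primary plus volume
currents).  Sensors are point magnetometers sensing along a unit orientation
vector.  A "multi-sphere" variant is supported through per-channel sphere
centers reusing the same closed form with shifted coordinates.

Orientation within the tangential plane is parametrized by an angle ``delta``
in [0, pi) measured from a deterministic azimuthal direction, see
:func:`tangential_basis`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "MU0",
    "SensorArray",
    "ConductorModel",
    "DipoleSpec",
    "LeadFieldVector",
    "DegenerateGeometryError",
    "tangential_basis",
    "dipole_field",
    "lead_field",
    "tangential_lead_fields",
]

MU0 = 4.0e-7 * np.pi  # vacuum permeability, T·m/A


class DegenerateGeometryError(ValueError):
    """Raised for geometrically degenerate forward-model inputs."""


@dataclass
class SensorArray:
    """Point-magnetometer array: positions (m) and unit sensing directions."""

    positions: np.ndarray
    orientations: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.orientations = np.atleast_2d(np.asarray(self.orientations, dtype=float))
        if self.positions.shape != self.orientations.shape:
            raise ValueError("positions and orientations must have equal shape")
        norms = np.linalg.norm(self.orientations, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise ValueError("orientations must be unit-norm to 1e-12")

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]

    def to_json(self, path) -> None:
        payload = {
            "positions_m": self.positions.tolist(),
            "orientations": self.orientations.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SensorArray":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(np.array(payload["positions_m"]), np.array(payload["orientations"]))


@dataclass
class ConductorModel:
    """Spherical conductor: a single center, or one center per channel."""

    center: np.ndarray
    per_channel_centers: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if self.per_channel_centers is not None:
            self.per_channel_centers = np.atleast_2d(
                np.asarray(self.per_channel_centers, dtype=float)
            )

    def centers_for(self, array: SensorArray) -> np.ndarray:
        """(M, 3) sphere center used for each channel."""
        if self.per_channel_centers is not None:
            if len(self.per_channel_centers) != array.n_channels:
                raise ValueError("per-channel center count must equal channel count")
            return self.per_channel_centers
        return np.broadcast_to(self.center, (array.n_channels, 3))

    def to_json(self, path) -> None:
        payload = {"center_m": self.center.tolist()}
        if self.per_channel_centers is not None:
            payload["per_channel_centers_m"] = self.per_channel_centers.tolist()
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ConductorModel":
        with open(path) as fh:
            payload = json.load(fh)
        per = payload.get("per_channel_centers_m")
        return cls(np.array(payload["center_m"]), None if per is None else np.array(per))


@dataclass
class DipoleSpec:
    """Dipolar source: location (m), tangential angle delta (rad), moment (A·m)."""

    location: np.ndarray
    delta: float = 0.0
    moment: float = 1.0

    def __post_init__(self) -> None:
        self.location = np.asarray(self.location, dtype=float).reshape(3)
        self.delta = float(self.delta) % np.pi


@dataclass
class LeadFieldVector:
    """Sensor-space pattern (T per A·m) of a unit-moment dipole."""

    values: np.ndarray
    source: DipoleSpec = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("lead field must be finite")


def tangential_basis(location, center):
    """Deterministic orthonormal basis of the tangential plane at ``location``.

    The first vector is the azimuthal direction ``normalize(z_hat x radial)``;
    when the radial direction is (numerically) parallel to z_hat the fallback
    ``x_hat x radial`` is used.  The second vector completes a right-handed
    triad with the radial direction.
    """
    location = np.asarray(location, dtype=float).reshape(3)
    center = np.asarray(center, dtype=float).reshape(3)
    radial = location - center
    r = np.linalg.norm(radial)
    if r < 1e-15:
        raise DegenerateGeometryError("location coincides with sphere center")
    radial = radial / r
    az = np.cross([0.0, 0.0, 1.0], radial)
    if np.linalg.norm(az) < 1e-9:
        az = np.cross([1.0, 0.0, 0.0], radial)
    az = az / np.linalg.norm(az)
    second = np.cross(radial, az)
    second = second / np.linalg.norm(second)
    return az, second


def dipole_field(sensor_pos, dipole_pos, moment_vec, center):
    """External magnetic field (T) of a current dipole in a spherical conductor.

    Vectorized over sensor positions ((M, 3) or (3,)).  ``center`` may be a
    single 3-vector or (M, 3) per-sensor centers.
    """
    sensor_pos = np.atleast_2d(np.asarray(sensor_pos, dtype=float))
    center = np.asarray(center, dtype=float)
    if center.ndim == 1:
        center = np.broadcast_to(center, sensor_pos.shape)
    q = np.asarray(moment_vec, dtype=float).reshape(3)

    r = sensor_pos - center  # sensor relative to sphere center
    r0 = np.asarray(dipole_pos, dtype=float).reshape(3) - center  # dipole ditto
    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=1)
    rn = np.linalg.norm(r, axis=1)
    if np.any(a < 1e-12):
        raise DegenerateGeometryError("sensor coincides with dipole location")
    if np.any(rn < 1e-12):
        raise DegenerateGeometryError("sensor at sphere center")

    r0r = np.einsum("ij,ij->i", np.broadcast_to(r0, r.shape), r)
    ar = np.einsum("ij,ij->i", a_vec, r)
    f = a * (rn * a + rn**2 - r0r)
    grad_f = (
        (a**2 / rn + ar / a + 2.0 * a + 2.0 * rn)[:, None] * r
        - (a + 2.0 * rn + ar / a)[:, None] * np.broadcast_to(r0, r.shape)
    )
    qxr0 = np.cross(np.broadcast_to(q, r.shape), np.broadcast_to(r0, r.shape))
    qxr0_r = np.einsum("ij,ij->i", qxr0, r)
    with np.errstate(invalid="ignore", divide="ignore"):
        b = MU0 / (4.0 * np.pi * f[:, None] ** 2) * (
            f[:, None] * qxr0 - qxr0_r[:, None] * grad_f
        )
    # a radial dipole (q x r0 == 0) is exactly silent; guard 0/0 at the center
    b = np.where(np.isfinite(b), b, 0.0)
    return b


def lead_field(array: SensorArray, conductor: ConductorModel, dipole: DipoleSpec):
    """Lead field of ``dipole`` at its tangential angle delta.

    The dipole must lie inside the sensor shell (all sensors farther from the
    sphere center than the dipole).  Output is in T per unit moment times the
    dipole's ``moment`` scale.
    """
    centers = conductor.centers_for(array)
    r0 = dipole.location - conductor.center
    sensor_r = np.linalg.norm(array.positions - conductor.center, axis=1)
    if np.any(np.linalg.norm(r0) >= sensor_r):
        raise ValueError("dipole must be strictly inside the sensor shell")
    e1, e2 = tangential_basis(dipole.location, conductor.center)
    moment_vec = dipole.moment * (np.cos(dipole.delta) * e1 + np.sin(dipole.delta) * e2)
    b = dipole_field(array.positions, dipole.location, moment_vec, centers)
    values = np.einsum("ij,ij->i", b, array.orientations)
    return LeadFieldVector(values, dipole)


def tangential_lead_fields(array: SensorArray, conductor: ConductorModel, location):
    """Lead fields of the two unit tangential basis dipoles at ``location``."""
    l1 = lead_field(array, conductor, DipoleSpec(location, delta=0.0))
    l2 = lead_field(array, conductor, DipoleSpec(location, delta=np.pi / 2.0))
    return l1.values, l2.values


def tangential_basis_grid(positions: np.ndarray, center: np.ndarray):
    """Vectorized :func:`tangential_basis` over (V, 3) positions."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    radial = positions - np.asarray(center, dtype=float)
    r = np.linalg.norm(radial, axis=1)
    if np.any(r < 1e-15):
        raise DegenerateGeometryError("a location coincides with the sphere center")
    radial = radial / r[:, None]
    az = np.cross(np.broadcast_to([0.0, 0.0, 1.0], radial.shape), radial)
    az_norm = np.linalg.norm(az, axis=1)
    polar = az_norm < 1e-9
    if polar.any():
        az[polar] = np.cross([1.0, 0.0, 0.0], radial[polar])
        az_norm = np.linalg.norm(az, axis=1)
    az = az / az_norm[:, None]
    second = np.cross(radial, az)
    second = second / np.linalg.norm(second, axis=1)[:, None]
    return az, second


def tangential_lead_fields_grid(
    array: SensorArray, conductor: ConductorModel, positions: np.ndarray
):
    """Tangential basis lead fields for many locations at once: two (V, M) arrays.

    Equivalent to calling :func:`tangential_lead_fields` per location but
    broadcast over the full (V, M) sensor-location product.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    centers = conductor.centers_for(array)  # (M, 3)
    e1, e2 = tangential_basis_grid(positions, conductor.center)

    r = array.positions[None, :, :] - centers[None, :, :]  # (1, M, 3)
    r0 = positions[:, None, :] - centers[None, :, :]  # (V, M, 3)
    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=2)
    rn = np.linalg.norm(r, axis=2)
    r0r = np.einsum("vmj,vmj->vm", r0, np.broadcast_to(r, r0.shape))
    ar = np.einsum("vmj,vmj->vm", a_vec, np.broadcast_to(r, a_vec.shape))
    f = a * (rn * a + rn**2 - r0r)
    grad_f = (
        (a**2 / rn + ar / a + 2.0 * a + 2.0 * rn)[:, :, None] * r
        - (a + 2.0 * rn + ar / a)[:, :, None] * r0
    )
    out = []
    for q_unit in (e1, e2):
        qxr0 = np.cross(np.broadcast_to(q_unit[:, None, :], r0.shape), r0)
        qxr0_r = np.einsum("vmj,vmj->vm", qxr0, np.broadcast_to(r, qxr0.shape))
        b = MU0 / (4.0 * np.pi * f[:, :, None] ** 2) * (
            f[:, :, None] * qxr0 - qxr0_r[:, :, None] * grad_f
        )
        out.append(np.einsum("vmj,mj->vm", b, array.orientations))
    return out[0], out[1]
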