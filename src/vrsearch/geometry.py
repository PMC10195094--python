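"""Spherical geometry for eye-in-space gaze analysis.

All gaze directions live on the unit sphere and are expressed as
(longitude, latitude) pairs in degrees at the API boundary:

* longitude in [-180, 180), positive to the participant's right,
  0 = straight ahead;
* latitude in [-90, 90], positive above the horizon.

Internally directions are converted to 3-D unit vectors and head
orientations to rotation matrices (via :class:`scipy.spatial.transform.Rotation`).
The head is treated as a roll-free rotation of the canonical forward axis
unless a full quaternion is supplied.

Gaze ("eye-in-space") is the composition of the head orientation with the
eye-in-head direction; distances between gaze samples are orthodromic
(great-circle) central angles, and sample-to-sample velocity is that
distance divided by the time step.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy.spatial.transform import Rotation


class InvalidSampleError(ValueError):
    """A gaze/head sample contains non-finite or out-of-range components."""


class DegenerateIntervalError(ValueError):
    """Timestamps are not strictly increasing (zero/negative interval)."""


class SphericalDirection(NamedTuple):
    """A direction on the unit sphere, degrees.

    ``lon`` in [-180, 180), positive rightward; ``lat`` in [-90, 90],
    positive above the horizon.
    """

    lon: float
    lat: float


_LAT_TOL = 1e-9


def wrap_longitude(lon):
    """Normalize longitudes to the half-open interval [-180, 180)."""
    return (np.asarray(lon, dtype=float) + 180.0) % 360.0 - 180.0


def _check_finite(*arrays) -> None:
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise InvalidSampleError("non-finite direction component")


def unit_vector(lon, lat) -> np.ndarray:
    """Convert (lon, lat) degrees to 3-D unit vectors, shape (..., 3).

    Axes: x = forward (lon=0, lat=0), y = rightward (lon=+90), z = up.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    _check_finite(lon, lat)
    if np.any(np.abs(lat) > 90.0 + _LAT_TOL):
        raise InvalidSampleError("latitude outside [-90, 90]")
    lam = np.radians(lon)
    phi = np.radians(np.clip(lat, -90.0, 90.0))
    cphi = np.cos(phi)
    return np.stack([cphi * np.cos(lam), cphi * np.sin(lam), np.sin(phi)], axis=-1)


def to_lonlat(vec) -> tuple[np.ndarray, np.ndarray]:
    """Convert 3-D vectors (any norm > 0) back to (lon, lat) degrees."""
    v = np.asarray(vec, dtype=float)
    _check_finite(v)
    norm = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(norm == 0.0):
        raise InvalidSampleError("zero-length direction vector")
    v = v / norm
    lat = np.degrees(np.arcsin(np.clip(v[..., 2], -1.0, 1.0)))
    lon = wrap_longitude(np.degrees(np.arctan2(v[..., 1], v[..., 0])))
    return lon, lat


def head_rotation(lon, lat, roll=0.0) -> Rotation:
    """Head orientation as a rotation of the canonical forward axis.

    Roll defaults to zero (the HMD export convention adopted here); a
    quaternion column set can be passed to :func:`combine_head_eye`
    instead when roll matters.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    roll = np.broadcast_to(np.asarray(roll, dtype=float), lon.shape)
    _check_finite(lon, lat, roll)
    angles = np.stack([lon, -lat, np.asarray(roll)], axis=-1)
    return Rotation.from_euler("ZYX", angles, degrees=True)


def head_rotation_from_quat(qw, qx, qy, qz) -> Rotation:
    """Head orientation from scalar-first quaternion components."""
    q = np.stack(
        [np.asarray(qx, float), np.asarray(qy, float), np.asarray(qz, float), np.asarray(qw, float)],
        axis=-1,
    )
    _check_finite(q)
    return Rotation.from_quat(q)


def combine_head_eye(head, eye_in_head) -> SphericalDirection | tuple[np.ndarray, np.ndarray]:
    """Compose head orientation and eye-in-head direction into gaze.

    ``head`` may be a (lon, lat) pair, a :class:`Rotation`, or a length-4
    quaternion (w, x, y, z). ``eye_in_head`` is a (lon, lat) pair (scalars
    or arrays). With an identity head orientation the eye-in-head
    direction is returned unchanged.
    """
    if isinstance(head, Rotation):
        rot = head
    else:
        head_arr = np.asarray(head, dtype=float)
        if head_arr.shape[-1] == 2:
            rot = head_rotation(head_arr[..., 0], head_arr[..., 1])
        elif head_arr.shape[-1] == 4:
            rot = head_rotation_from_quat(
                head_arr[..., 0], head_arr[..., 1], head_arr[..., 2], head_arr[..., 3]
            )
        else:
            raise InvalidSampleError("head must be (lon, lat) or quaternion (w, x, y, z)")
    eye = np.asarray(eye_in_head, dtype=float)
    vec = rot.apply(unit_vector(eye[..., 0], eye[..., 1]))
    lon, lat = to_lonlat(vec)
    if np.ndim(lon) == 0:
        return SphericalDirection(float(lon), float(lat))
    return lon, lat


def orthodromic_distance(lon1, lat1, lon2, lat2) -> np.ndarray | float:
    """Great-circle central angle between directions, in degrees [0, 180].

    Uses the numerically stable arctan2 form (accurate for both nearly
    identical and nearly antipodal directions).
    """
    a = unit_vector(lon1, lat1)
    b = unit_vector(lon2, lat2)
    cross = np.linalg.norm(np.cross(a, b), axis=-1)
    dot = np.sum(a * b, axis=-1)
    ang = np.degrees(np.arctan2(cross, dot))
    if np.ndim(ang) == 0:
        return float(ang)
    return ang


def angular_velocity(t, lon, lat) -> np.ndarray:
    """Sample-to-sample gaze speed in degrees/second.

    Returns one value per inter-sample interval (length ``n - 1``): the
    orthodromic distance between consecutive samples divided by the time
    difference. Timestamps must be strictly increasing.
    """
    t = np.asarray(t, dtype=float)
    if t.size < 2:
        raise DegenerateIntervalError("need at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0.0):
        raise DegenerateIntervalError("timestamps must be strictly increasing")
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    dist = orthodromic_distance(lon[:-1], lat[:-1], lon[1:], lat[1:])
    return np.asarray(dist) / dt


def spherical_mean(lon, lat) -> SphericalDirection:
    """Direction of the mean unit vector of a set of directions."""
    v = unit_vector(lon, lat)
    m = v.mean(axis=0) if v.ndim > 1 else v
    mlon, mlat = to_lonlat(m)
    return SphericalDirection(float(mlon), float(mlat))


def slerp(lon0, lat0, lon1, lat1, frac) -> tuple[np.ndarray, np.ndarray]:
    """Great-circle interpolation between two directions.

    ``frac`` is the arc fraction in [0, 1] (scalar or array). Degenerate
    (identical) endpoints return the start direction.
    """
    u = unit_vector(lon0, lat0)
    v = unit_vector(lon1, lat1)
    frac = np.asarray(frac, dtype=float)
    omega = np.radians(orthodromic_distance(lon0, lat0, lon1, lat1))
    if omega < 1e-12:
        lon = np.full(frac.shape, float(wrap_longitude(lon0)))
        lat = np.full(frac.shape, float(lat0))
        return lon, lat
    so = np.sin(omega)
    w = (np.sin((1.0 - frac) * omega) / so)[..., None] * u + (np.sin(frac * omega) / so)[..., None] * v
    return to_lonlat(w)
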