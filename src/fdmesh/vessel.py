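"""Centerline-based vessel representation.

A vessel is an ordered polyline of centerline samples — arc length ``s``
(mm, strictly increasing, 0 at the *distal* end, matching how flow
diverters are anchored distally), 3-D position (mm) and lumen radius (mm)
— together with curvature estimates derived from it.  The aneurysm is
represented as a half-open arc-length interval ``[s_start, s_end)``
covering the neck on the centerline, plus a scalar morphology record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CenterlineParseError, GeometryError

__all__ = [
    "VesselModel",
    "AneurysmRegion",
    "AneurysmMorphology",
    "read_centerline",
    "write_centerline",
    "resample_centerline",
    "curvature_at",
    "diameter_at",
]

CENTERLINE_COLUMNS = ("s_mm", "x_mm", "y_mm", "z_mm", "radius_mm")

#: Reference vector used to seed cross-section frames and the normal of
#: straight segments; fixed so repeated runs are bit-reproducible.
_REFERENCE_VECTOR = np.array([0.0, 0.0, 1.0])

_STRAIGHT_TOL = 1e-8  # 1/mm; below this a segment counts as straight


@dataclass
class VesselModel:
    """Ordered centerline samples with radii."""

    s: np.ndarray          # (n,) arc length, mm, strictly increasing from 0
    pos: np.ndarray        # (n, 3) positions, mm
    radius: np.ndarray     # (n,) lumen radii, mm
    name: str = ""
    _kappa: np.ndarray | None = field(default=None, repr=False, compare=False)
    _normal: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.pos = np.asarray(self.pos, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        n = self.s.shape[0]
        if n < 4:
            raise GeometryError(f"vessel needs at least 4 samples, got {n}")
        if self.pos.shape != (n, 3) or self.radius.shape != (n,):
            raise GeometryError("inconsistent sample array shapes")
        if abs(self.s[0]) > 1e-9:
            raise GeometryError(f"arc length must start at 0, got s[0]={self.s[0]}")
        if not np.all(np.diff(self.s) > 0):
            raise GeometryError("arc length must be strictly increasing")
        if not np.all(self.radius > 0):
            raise GeometryError("all radii must be positive")

    @property
    def total_length(self) -> float:
        return float(self.s[-1])

    def _curvature_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-sample curvature magnitude and unit normal (toward center)."""
        if self._kappa is None:
            d1 = np.gradient(self.pos, self.s, axis=0)
            d2 = np.gradient(d1, self.s, axis=0)
            speed = np.linalg.norm(d1, axis=1)
            cross = np.cross(d1, d2)
            kappa = np.linalg.norm(cross, axis=1) / np.maximum(speed, 1e-300) ** 3
            # normal = component of d2 orthogonal to the tangent
            tang = d1 / speed[:, None]
            d2_perp = d2 - (np.sum(d2 * tang, axis=1))[:, None] * tang
            norms = np.linalg.norm(d2_perp, axis=1)
            normal = np.zeros_like(d2_perp)
            curved = kappa > _STRAIGHT_TOL
            normal[curved] = d2_perp[curved] / norms[curved, None]
            if np.any(~curved):
                normal[~curved] = _straight_normal(tang[~curved])
            kappa[~curved] = 0.0
            self._kappa, self._normal = kappa, normal
        return self._kappa, self._normal


def _straight_normal(tangents: np.ndarray) -> np.ndarray:
    """Deterministic unit normal for straight segments: Gram-Schmidt of the
    fixed reference vector against the tangent (falling back to x-hat when
    the tangent is parallel to the reference)."""
    t = np.atleast_2d(tangents)
    ref = np.broadcast_to(_REFERENCE_VECTOR, t.shape).copy()
    parallel = np.abs(np.sum(ref * t, axis=1)) > 0.999
    ref[parallel] = np.array([1.0, 0.0, 0.0])
    n = ref - np.sum(ref * t, axis=1)[:, None] * t
    return n / np.linalg.norm(n, axis=1)[:, None]


def read_centerline(path, name: str | None = None) -> VesselModel:
    """Read a centerline CSV with header ``s_mm,x_mm,y_mm,z_mm,radius_mm``.

    Lines starting with ``#`` are metadata comments.  Parse errors name the
    offending data row (1-based, excluding header/comments).
    """
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # noqa: BLE001 - surface as schema error
        raise CenterlineParseError(f"cannot parse centerline file {path}: {exc}") from exc
    missing = [c for c in CENTERLINE_COLUMNS if c not in df.columns]
    if missing:
        raise CenterlineParseError(f"{path}: missing columns {missing}")
    arr = df[list(CENTERLINE_COLUMNS)].to_numpy(dtype=float)
    if np.any(~np.isfinite(arr)):
        row = int(np.argwhere(~np.isfinite(arr).all(axis=1))[0, 0]) + 1
        raise CenterlineParseError(f"{path}: malformed value at data row {row}")
    bad_r = np.flatnonzero(arr[:, 4] <= 0)
    if bad_r.size:
        raise CenterlineParseError(
            f"{path}: non-positive radius at data row {int(bad_r[0]) + 1}"
        )
    ds = np.diff(arr[:, 0])
    if np.any(ds <= 0):
        row = int(np.flatnonzero(ds <= 0)[0]) + 2
        raise CenterlineParseError(
            f"{path}: arc length not strictly increasing at data row {row}"
        )
    return VesselModel(
        s=arr[:, 0], pos=arr[:, 1:4], radius=arr[:, 4],
        name=name if name is not None else str(path),
    )


def write_centerline(vessel: VesselModel, path, metadata: dict | None = None) -> None:
    """Write the centerline CSV (17 significant digits, round-trip safe)."""
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        fh.write(",".join(CENTERLINE_COLUMNS) + "\n")
        for i in range(vessel.s.shape[0]):
            row = (vessel.s[i], *vessel.pos[i], vessel.radius[i])
            fh.write(",".join(f"{v:.17g}" for v in row) + "\n")


def resample_centerline(vessel: VesselModel, ds: float) -> VesselModel:
    """Resample at a uniform arc-length grid by linear interpolation.

    The grid is ``linspace(0, L, round(L/ds) + 1)`` so both endpoints are
    preserved exactly and the realized spacing is within half a step of the
    requested ``ds``.  Resampling twice at the same ``ds`` is a no-op.
    """
    L = vessel.total_length
    if not 0 < ds < L:
        raise GeometryError(f"ds={ds} must lie in (0, total length={L})")
    n_seg = max(3, round(L / ds))
    grid = np.linspace(0.0, L, n_seg + 1)
    pos = np.column_stack([np.interp(grid, vessel.s, vessel.pos[:, k]) for k in range(3)])
    radius = np.interp(grid, vessel.s, vessel.radius)
    return VesselModel(s=grid, pos=pos, radius=radius, name=vessel.name)


def curvature_at(vessel: VesselModel, s: float) -> tuple[float, np.ndarray]:
    """Centerline curvature (1/mm) and unit normal toward the curvature
    center at arc length ``s`` (clamped to the domain).

    The curvature magnitude is linearly interpolated between the discrete
    second-difference estimates at the samples; the normal is taken from
    the nearest sample (unit vectors do not interpolate linearly).  For
    straight segments (kappa below 1e-8/mm) kappa is exactly 0 and the
    normal is the fixed documented reference direction.
    """
    kappa, normal = vessel._curvature_arrays()
    s = float(np.clip(s, 0.0, vessel.total_length))
    k = float(np.interp(s, vessel.s, kappa))
    idx = int(np.argmin(np.abs(vessel.s - s)))
    return k, normal[idx]


def diameter_at(vessel: VesselModel, s) -> float:
    """Lumen diameter 2*r(s), linear in s, clamped to the domain."""
    d = 2.0 * np.interp(s, vessel.s, vessel.radius)
    return float(d) if np.ndim(d) == 0 else d


@dataclass(frozen=True)
class AneurysmRegion:
    """Half-open arc-length interval [s_start, s_end) covering the neck."""

    s_start: float
    s_end: float

    def __post_init__(self) -> None:
        if not 0 <= self.s_start < self.s_end:
            raise GeometryError(
                f"invalid aneurysm region [{self.s_start}, {self.s_end})"
            )

    def contains(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        return (s >= self.s_start) & (s < self.s_end)


@dataclass(frozen=True)
class AneurysmMorphology:
    """Scalar aneurysm descriptors (all mm except volume, mm^3)."""

    depth: float
    width: float
    volume: float
    neck_max: float
    neck_min: float

    def __post_init__(self) -> None:
        for name in ("depth", "width", "volume", "neck_max", "neck_min"):
            if not getattr(self, name) > 0:
                raise GeometryError(f"AneurysmMorphology.{name} must be positive")
        if self.neck_min > self.neck_max:
            raise GeometryError("neck_min must not exceed neck_max")
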