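"""Virtual deployment of a braided device along a vessel centerline.

The device is marched row by row from its distal anchor toward the
proximal end.  Each cell row takes the local vessel diameter (capped at
the nominal device diameter — a braid cannot expand past nominal), which
sets the local half angle via the angle–diameter calibration, and hence
the row length ``2 S cos(alpha)``: an under-expanded braid lengthens
(foreshortening in reverse).  The row count is fixed by the device spec,
acting as the surrogate for wire-length conservation.

On top of the per-row state, vessel curvature modulates the mesh around
the circumference: the inner side of a bend is longitudinally compressed
(strain ``eps = -kappa * r * cos(theta - theta_normal)``), which tilts the
local half angle via ``cos(alpha_local) = cos(alpha_row) * (1 + eps)``.
For rows with ``alpha_row > 45°`` this closes the mesh (lower porosity) on
the inner wall, reproducing the characteristic inner/outer asymmetry of
deployed flow diverters; the ordering reverses below 45°, where the cell
area peaks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .device import (
    DeviceSpec,
    cell_porosity,
    nominal_row_count,
    valid_angle_range,
)
from .errors import DeploymentError, GeometryError
from .vessel import AneurysmRegion, VesselModel

__all__ = ["DeployedDevice", "MeshSummary", "deploy", "deployed_length",
           "region_summary", "field_frame"]

#: small-strain clamp for the curvature modulation
_MAX_STRAIN = 0.5


@dataclass
class DeployedDevice:
    """Per-row and per-circumferential-sample state of a deployed device.

    Field arrays are (n_rows, n_theta), row-major with theta ascending.
    ``mesh_angle`` is the full crossing angle ``2*alpha`` in degrees on the
    0°(closed)–180°(open) scale; ``expansion`` is percent of nominal
    diameter.
    """

    spec: DeviceSpec
    s_center: np.ndarray        # (M,) mm
    local_diameter: np.ndarray  # (M,) mm
    alpha_row: np.ndarray       # (M,) degrees
    row_length: np.ndarray      # (M,) mm
    kappa: np.ndarray           # (M,) 1/mm at the row center
    theta_normal: np.ndarray    # (M,) degrees; direction of the inner wall
    theta: np.ndarray           # (n_theta,) degrees
    porosity: np.ndarray        # (M, n_theta)
    mesh_angle: np.ndarray      # (M, n_theta) degrees
    expansion: np.ndarray       # (M, n_theta) percent

    @property
    def n_rows(self) -> int:
        return int(self.s_center.shape[0])


@dataclass(frozen=True)
class MeshSummary:
    """Mean/SD of the three mesh fields over a set of device points."""

    porosity_mean: float
    porosity_sd: float
    angle_mean: float
    angle_sd: float
    expansion_mean: float
    expansion_sd: float
    n_points: int


def deploy(spec: DeviceSpec, vessel: VesselModel, distal_s: float,
           n_theta: int = 16) -> DeployedDevice:
    """Deploy ``spec`` into ``vessel`` with its distal end at ``distal_s``.

    Rows are placed sequentially from ``distal_s`` proximally (increasing
    arc length).  Per row, the center diameter is found by a short fixed
    point iteration (row length depends on the diameter at the row center,
    which depends on the row length), then the circumferential fields are
    evaluated on ``n_theta`` equally spaced samples.

    Raises
    ------
    DeploymentError
        If the device overruns the vessel (reports rows placed) or the
        vessel is so narrow the half angle leaves the valid range (names
        the arc length).
    """
    if n_theta < 8:
        raise GeometryError(f"n_theta must be >= 8, got {n_theta}")
    if not 0 <= distal_s < vessel.total_length:
        raise GeometryError(f"distal_s={distal_s} outside vessel [0, {vessel.total_length})")

    M = nominal_row_count(spec)
    a_min, a_max = valid_angle_range(spec)
    sin_nom = math.sin(math.radians(spec.alpha_nom))
    phi = spec.phi_nom
    S = spec.S

    # uniform radius grid for O(1) scalar lookups inside the placement loop
    sv, rv = vessel.s, vessel.radius
    L_total = vessel.total_length
    n_grid = max(64, int(L_total / 0.25))
    gs = np.linspace(0.0, L_total, n_grid + 1)
    gr = np.interp(gs, sv, rv)
    inv_h = n_grid / L_total

    def diam(s: float) -> float:
        x = s * inv_h
        k = int(x)
        if k >= n_grid:
            return 2.0 * gr[n_grid]
        t = x - k
        return 2.0 * ((1.0 - t) * gr[k] + t * gr[k + 1])

    s_center = np.empty(M)
    local_d = np.empty(M)
    alpha_row = np.empty(M)
    row_len = np.empty(M)

    p = float(distal_s)
    rl = 2.0 * S * math.cos(math.radians(spec.alpha_nom))
    for i in range(M):
        for _ in range(3):
            sc = p + 0.5 * rl
            if sc > L_total:
                raise DeploymentError(
                    f"device overruns vessel after {i} of {M} rows "
                    f"(at s={p:.2f} mm of {L_total:.2f} mm)"
                )
            d = min(diam(sc), phi)
            sin_a = sin_nom * d / phi
            a = math.degrees(math.asin(sin_a))
            rl = 2.0 * S * math.sqrt(1.0 - sin_a * sin_a)
        if a < a_min:
            raise DeploymentError(
                f"vessel diameter {d:.3f} mm at s={sc:.2f} mm drives the half angle "
                f"below the valid range ({a_min:.3f} deg) for {spec.brand_label!r}"
            )
        s_center[i], local_d[i], alpha_row[i], row_len[i] = sc, d, a, rl
        p += rl
        if p > L_total * (1 + 1e-9):
            raise DeploymentError(
                f"device overruns vessel after {i + 1} of {M} rows "
                f"(needs {p:.2f} mm, vessel has {L_total:.2f} mm)"
            )

    # curvature and inner-wall direction per row
    kappa_s, normal_s = vessel._curvature_arrays()
    kappa = np.interp(s_center, sv, kappa_s)
    idx = np.searchsorted(sv, s_center)
    idx = np.clip(idx, 1, sv.size - 1)
    idx -= (s_center - sv[idx - 1]) < (sv[idx] - s_center)  # nearest sample
    normals = normal_s[idx]

    # cross-section frame: e1 = reference Gram-Schmidt'd against tangent,
    # e2 = t x e1; theta_normal = angle of the curvature normal in (e1, e2)
    d1 = np.gradient(vessel.pos, sv, axis=0)
    tang_s = d1 / np.linalg.norm(d1, axis=1)[:, None]
    tang = tang_s[idx]
    from .vessel import _straight_normal  # fixed reference frame seed
    e1 = _straight_normal(tang)
    e2 = np.cross(tang, e1)
    theta_normal = np.degrees(np.arctan2(np.sum(normals * e2, axis=1),
                                         np.sum(normals * e1, axis=1)))
    theta_normal[kappa <= 0.0] = 0.0

    theta = np.arange(n_theta) * (360.0 / n_theta)
    eps = -kappa[:, None] * (local_d[:, None] / 2.0) * np.cos(
        np.radians(theta[None, :] - theta_normal[:, None])
    )
    np.clip(eps, -_MAX_STRAIN, _MAX_STRAIN, out=eps)
    cos_local = np.cos(np.radians(alpha_row))[:, None] * (1.0 + eps)
    cos_lo = math.cos(math.radians(a_max))  # alpha clamped into valid range
    cos_hi = math.cos(math.radians(max(a_min, 1e-9)))
    alpha_local = np.degrees(np.arccos(np.clip(cos_local, cos_lo, min(cos_hi, 1.0))))
    porosity = cell_porosity(S, spec.omega, alpha_local, check=False)
    np.clip(porosity, 0.0, 1.0, out=porosity)

    expansion = np.broadcast_to(
        (100.0 * local_d / phi)[:, None], alpha_local.shape
    ).copy()

    return DeployedDevice(
        spec=spec, s_center=s_center, local_diameter=local_d,
        alpha_row=alpha_row, row_length=row_len, kappa=kappa,
        theta_normal=theta_normal, theta=theta,
        porosity=porosity, mesh_angle=2.0 * alpha_local, expansion=expansion,
    )


def deployed_length(dev: DeployedDevice) -> float:
    """Total deployed length, mm (sum of row lengths)."""
    return float(np.sum(dev.row_length))


def region_summary(dev: DeployedDevice, region: AneurysmRegion) -> MeshSummary:
    """Mean and population SD of porosity, mesh angle and expansion over
    all circumferential samples of rows whose center falls in ``region``."""
    mask = region.contains(dev.s_center)
    if not np.any(mask):
        raise DeploymentError(
            f"no device row centers inside region [{region.s_start:.2f}, "
            f"{region.s_end:.2f}) mm"
        )
    por = dev.porosity[mask].ravel()
    ang = dev.mesh_angle[mask].ravel()
    exp = dev.expansion[mask].ravel()
    return MeshSummary(
        porosity_mean=float(por.mean()), porosity_sd=float(por.std()),
        angle_mean=float(ang.mean()), angle_sd=float(ang.std()),
        expansion_mean=float(exp.mean()), expansion_sd=float(exp.std()),
        n_points=int(por.size),
    )


def field_frame(dev: DeployedDevice) -> pd.DataFrame:
    """Tidy per-point field table (row-major, theta ascending)."""
    M, T = dev.porosity.shape
    return pd.DataFrame({
        "s_mm": np.repeat(dev.s_center, T),
        "theta_deg": np.tile(dev.theta, M),
        "porosity": dev.porosity.ravel(),
        "coverage": 1.0 - dev.porosity.ravel(),
        "mesh_angle_deg": dev.mesh_angle.ravel(),
        "expansion_pct": dev.expansion.ravel(),
    })
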