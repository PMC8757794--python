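"""Closed-form geometry of the braided flow-diverter unit cell.

A braided flow diverter is a tube of ``n_wires`` helical wires, half wound
clockwise and half counter-clockwise.  The crossings tile the tube surface
with congruent rhombi ("unit pore cells") of side ``S`` (the strut length,
constant for a given device) bounded by wires of width ``omega``.  The half
angle ``alpha`` between a strut and the longitudinal axis of the device is
the single degree of freedom: crimping the device closes the cells
(``alpha`` → small), over-expansion opens them toward the circumferential
direction.  Everything this module computes follows from that rhombus.

Angles are degrees at every public interface; radians are used internally.
The device-level "mesh angle" reported elsewhere in the package is the full
wire-crossing angle ``2*alpha`` on a 0°(closed)–180°(open) scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .errors import ConfigurationError, GeometryError

__all__ = [
    "DeviceSpec",
    "UnitCellState",
    "cell_metal_fraction",
    "cell_porosity",
    "halfangle_at_diameter",
    "nominal_row_count",
    "valid_angle_range",
    "nominal_porosity",
    "unit_cell_state",
    "load_presets",
    "get_preset",
]


@dataclass(frozen=True)
class DeviceSpec:
    """Design parameters of a braided flow diverter.

    Parameters
    ----------
    brand_label
        Free-text label (e.g. a brand name); not interpreted.
    phi_nom
        Nominal (fully expanded) diameter, mm.
    L_nom
        Device length at nominal expansion, mm.
    n_wires
        Total wire count; must be even (half per helix direction), >= 4.
    S
        Strut length (wire-crossing to wire-crossing), mm.
    omega
        Wire / strut width, mm; must be smaller than ``S``.
    alpha_nom
        Nominal half angle between strut and longitudinal axis, degrees,
        strictly inside (0, 90).
    """

    brand_label: str
    phi_nom: float
    L_nom: float
    n_wires: int
    S: float
    omega: float
    alpha_nom: float

    def __post_init__(self) -> None:
        for name in ("phi_nom", "L_nom", "S", "omega"):
            v = getattr(self, name)
            if not (name == "omega" and v == 0) and not v > 0:
                raise ConfigurationError(f"DeviceSpec.{name} must be > 0, got {v!r}")
        if self.omega < 0 or not self.omega < self.S:
            raise ConfigurationError(
                f"strut width omega={self.omega} must satisfy 0 <= omega < S={self.S}"
            )
        if not 0 < self.alpha_nom < 90:
            raise ConfigurationError(
                f"alpha_nom must lie in (0, 90) degrees, got {self.alpha_nom}"
            )
        if self.n_wires < 4 or self.n_wires % 2:
            raise ConfigurationError(
                f"n_wires must be an even integer >= 4, got {self.n_wires}"
            )


@dataclass(frozen=True)
class UnitCellState:
    """Unit-cell geometry at one local half angle."""

    alpha: float          # degrees
    cell_area: float      # mm^2, rhombus area S^2 sin 2a
    metal_area: float     # mm^2, strut-covered area within the cell
    porosity: float       # free fraction, 1 - metal_area/cell_area


def _check_angle(S: float, omega: float, alpha) -> None:
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    if np.any(alpha <= 0) or np.any(alpha >= 90):
        bad = float(alpha[(alpha <= 0) | (alpha >= 90)][0])
        raise GeometryError(f"half angle {bad} deg outside (0, 90)")
    lo, hi = _range_from_closed_form(S, omega)
    eps = 1e-9
    if np.any(alpha < lo - eps) or np.any(alpha > hi + eps):
        bad = float(alpha[(alpha < lo - eps) | (alpha > hi + eps)][0])
        raise GeometryError(
            f"half angle {bad} deg outside the valid range "
            f"({lo:.4f}, {hi:.4f}) deg for S={S}, omega={omega}"
        )


def cell_metal_fraction(S: float, omega: float, alpha, *, check: bool = True):
    """Metal-covered fraction of the unit pore cell.

    The rhombus cell has area ``S^2 sin 2a``.  Each cell owns two full
    struts (four half-shared edges) of area ``2 S omega``, minus one
    wire-crossing overlap — the parallelogram where two ``omega``-wide
    strips meet at included angle ``2a`` — of area ``omega^2 / sin 2a``:

        f(a) = (2 S omega - omega^2 / sin 2a) / (S^2 sin 2a)

    Parameters are mm and degrees; ``alpha`` may be an array.
    """
    if check:
        _check_angle(S, omega, alpha)
    alpha = np.asarray(alpha, dtype=float)
    s2a = np.sin(np.radians(2.0 * alpha))
    f = (2.0 * S * omega - omega**2 / s2a) / (S**2 * s2a)
    return f if f.ndim else float(f)


def cell_porosity(S: float, omega: float, alpha, *, check: bool = True):
    """Free (non-metal) fraction of the unit cell: ``1 - cell_metal_fraction``."""
    f = cell_metal_fraction(S, omega, alpha, check=check)
    return 1.0 - f


def unit_cell_state(S: float, omega: float, alpha: float) -> UnitCellState:
    """Assemble the full unit-cell bookkeeping at one half angle."""
    _check_angle(S, omega, alpha)
    cell_area = S**2 * math.sin(math.radians(2.0 * alpha))
    f = cell_metal_fraction(S, omega, alpha, check=False)
    return UnitCellState(
        alpha=float(alpha),
        cell_area=cell_area,
        metal_area=f * cell_area,
        porosity=1.0 - f,
    )


def halfangle_at_diameter(spec: DeviceSpec, d) -> float:
    """Local half angle at deployed diameter ``d`` (mm), degrees.

    With fixed strut length and a fixed number of crossings per
    circumference, the circumferential span of a cell is proportional both
    to the local diameter and to ``sin(alpha)``, so

        alpha(d) = arcsin( sin(alpha_nom) * d / phi_nom )

    which returns ``alpha_nom`` exactly at the nominal diameter.  Callers
    clamp oversizing (``d > phi_nom``) before calling.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0) or np.any(d > spec.phi_nom * (1 + 1e-12)):
        d1 = np.atleast_1d(d)
        bad = float(d1[(d1 <= 0) | (d1 > spec.phi_nom * (1 + 1e-12))][0])
        raise GeometryError(
            f"diameter {bad} mm outside (0, phi_nom={spec.phi_nom}] — clamp oversizing first"
        )
    a = np.degrees(
        np.arcsin(np.sin(np.radians(spec.alpha_nom)) * np.minimum(d, spec.phi_nom) / spec.phi_nom)
    )
    return a if a.ndim else float(a)


def nominal_row_count(spec: DeviceSpec) -> int:
    """Number of longitudinal cell rows, fixed per device.

    One row of cells spans ``2 S cos(alpha)`` longitudinally (the long
    rhombus diagonal at nominal).  The count ``M = round(L_nom / (2 S cos
    alpha_nom))`` is conserved across deployments — the discrete surrogate
    for conservation of wire length.
    """
    row_len = 2.0 * spec.S * math.cos(math.radians(spec.alpha_nom))
    M = round(spec.L_nom / row_len)
    if M < 1:
        raise ConfigurationError(
            f"device {spec.brand_label!r} is shorter than one cell row "
            f"(L_nom={spec.L_nom} mm, nominal row length {row_len:.4f} mm)"
        )
    return M


def _range_from_closed_form(S: float, omega: float) -> tuple[float, float]:
    """Valid half-angle interval, degrees, via bisection.

    The metal fraction saturates at exactly 1 where the crossing overlap
    fills the cell, i.e. where ``S sin 2a = omega``; beyond it wires overlap
    their neighbours and the closed form loses meaning.  The closed form
    minus 1 has a double root there, so bisection is run on the monotone
    saturation condition ``g(a) = omega - S sin 2a`` over a in (0, 45].
    """
    if omega == 0.0:
        return 0.0, 90.0
    lo, hi = 0.0, 45.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if omega - S * math.sin(math.radians(2.0 * mid)) > 0.0:
            lo = mid
        else:
            hi = mid
    a_min = 0.5 * (lo + hi)
    return a_min, 90.0 - a_min


def valid_angle_range(spec: DeviceSpec) -> tuple[float, float]:
    """Half-angle interval (degrees) on which the unit cell is physical.

    Inside the interval the metal fraction lies in [0, 1]; at both
    endpoints it equals 1 (fully closed mesh).  In practice neither bound
    is reached by a deployed device.
    """
    return _range_from_closed_form(spec.S, spec.omega)


def nominal_porosity(spec: DeviceSpec) -> float:
    """Porosity at nominal expansion — the manufacturer-tag baseline."""
    return cell_porosity(spec.S, spec.omega, spec.alpha_nom)


# ---------------------------------------------------------------------------
# presets

_PRESET_KEYS = {
    "brand_label", "phi_nom_mm", "L_nom_mm", "n_wires",
    "strut_len_mm", "strut_width_mm", "alpha_nom_deg",
}


def _spec_from_entry(entry: dict) -> DeviceSpec:
    unknown = set(entry) - _PRESET_KEYS - {"note"}
    if unknown:
        raise ConfigurationError(f"unknown device-spec keys: {sorted(unknown)}")
    missing = _PRESET_KEYS - set(entry)
    if missing:
        raise ConfigurationError(f"device spec missing keys: {sorted(missing)}")
    return DeviceSpec(
        brand_label=entry["brand_label"],
        phi_nom=float(entry["phi_nom_mm"]),
        L_nom=float(entry["L_nom_mm"]),
        n_wires=int(entry["n_wires"]),
        S=float(entry["strut_len_mm"]),
        omega=float(entry["strut_width_mm"]),
        alpha_nom=float(entry["alpha_nom_deg"]),
    )


def load_presets() -> dict[str, DeviceSpec]:
    """Bundled illustrative device presets, keyed by brand label.

    The four entries carry the brand labels of the cohort they emulate but
    are *not* manufacturer data: wire counts, strut dimensions and braiding
    angles are illustrative values calibrated so the nominal porosities sit
    in the plausible 0.65–0.80 band.
    """
    text = resources.files("fdmesh").joinpath("data/presets.json").read_text()
    raw = json.loads(text)
    return {e["brand_label"]: _spec_from_entry(e) for e in raw["devices"]}


def read_device_spec(path) -> DeviceSpec:
    """Read a single device spec from a JSON file (schema as in presets)."""
    with open(path) as fh:
        return _spec_from_entry(json.load(fh))


def get_preset(brand_label: str) -> DeviceSpec:
    presets = load_presets()
    try:
        return presets[brand_label]
    except KeyError:
        raise ConfigurationError(
            f"no preset named {brand_label!r}; available: {sorted(presets)}"
        ) from None
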