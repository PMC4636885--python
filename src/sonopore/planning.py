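"""Treatment-plane selection and cross-talk analysis for the transducer array.

The device operates in the near field, so the treatment plane is chosen to
minimize field heterogeneity: for each candidate axial distance, a planar
scan is reduced to the population standard deviation of pressure over a
circular mask centred on the acoustic axis, and the distance with the
smallest value wins. On the chosen plane, a grid point of ~90% relative
intensity serves as the electrical-power calibration point, and a wide scan
quantifies how much intensity leaks into a neighbouring transducer's
treatment area (cross-talk, in dB relative to the plane maximum).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage import measure

from .exceptions import DegenerateDataError
from .piston_field import PlanarScan

__all__ = [
    "HeterogeneityCurve",
    "TreatmentPlan",
    "heterogeneity",
    "optimal_distance",
    "calibration_point",
    "crosstalk_db",
    "crosstalk_contours",
    "plan_treatment",
]

#: Inscribed-circle radius of the standard 10.5 x 10.5 mm characterization
#: scan; the default mask for heterogeneity.
DEFAULT_MASK_RADIUS_MM = 5.25

#: Lateral offset, mm, of the nearest edge of a neighbouring crystal:
#: 26 mm housing pitch minus the 10 mm crystal radius.
NEIGHBOR_EDGE_OFFSET_MM = 16.0


def _circular_mask(scan: PlanarScan, mask_radius_mm: float) -> np.ndarray:
    xg, yg = np.meshgrid(scan.x_mm, scan.y_mm, indexing="ij")
    return xg**2 + yg**2 <= mask_radius_mm**2


def heterogeneity(scan: PlanarScan, mask_radius_mm: float | None = None) -> float:
    """Population standard deviation of pressure within the circular mask.

    The mask is centred on the acoustic axis (x = y = 0). Raises
    :class:`DegenerateDataError` if fewer than two grid points fall inside.
    """
    if mask_radius_mm is None:
        mask_radius_mm = DEFAULT_MASK_RADIUS_MM
    if mask_radius_mm <= 0:
        raise ValueError("mask_radius must be positive")
    m = _circular_mask(scan, mask_radius_mm)
    if m.sum() < 2:
        raise DegenerateDataError(
            "circular mask contains fewer than two grid points"
        )
    return float(np.std(scan.pressure[m]))


@dataclass
class HeterogeneityCurve:
    """Heterogeneity of each candidate slice along the axis."""

    z_mm: np.ndarray
    heterogeneity: np.ndarray
    mask_radius_mm: float

    def __post_init__(self) -> None:
        self.z_mm = np.asarray(self.z_mm, dtype=float)
        self.heterogeneity = np.asarray(self.heterogeneity, dtype=float)
        if self.z_mm.size != self.heterogeneity.size:
            raise ValueError("lengths must match")
        if np.any(self.heterogeneity < 0):
            raise ValueError("heterogeneity must be nonnegative")

    def plot(self, ax=None):
        """Line plot of heterogeneity vs axial distance."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.z_mm, self.heterogeneity, marker="o")
        ax.set_xlabel("axial distance z (mm)")
        ax.set_ylabel("heterogeneity (std of pressure, rel. units)")
        return ax


@dataclass
class OptimalDistanceResult:
    optimal_z_mm: float
    heterogeneity_at_optimum: float
    curve: HeterogeneityCurve


@dataclass
class TreatmentPlan:
    """Everything characterization decides for one transducer."""

    optimal_z_mm: float
    heterogeneity_at_optimum: float
    calibration_point: tuple  # (x_mm, y_mm, relative_intensity)
    crosstalk_db_at_neighbor: float | None
    curve: HeterogeneityCurve | None = None

    def to_dict(self) -> dict:
        d = {
            "optimal_z_mm": self.optimal_z_mm,
            "heterogeneity_at_optimum": self.heterogeneity_at_optimum,
            "calibration_point": {
                "x_mm": self.calibration_point[0],
                "y_mm": self.calibration_point[1],
                "relative_intensity": self.calibration_point[2],
            },
            "crosstalk_db_at_neighbor": self.crosstalk_db_at_neighbor,
        }
        if self.curve is not None:
            d["heterogeneity_curve"] = {
                "z_mm": self.curve.z_mm.tolist(),
                "heterogeneity": self.curve.heterogeneity.tolist(),
                "mask_radius_mm": self.curve.mask_radius_mm,
            }
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def optimal_distance(
    scans: Sequence[PlanarScan], mask_radius_mm: float | None = None
) -> OptimalDistanceResult:
    """Choose the axial distance whose slice has minimal heterogeneity.

    Ties are broken toward the smaller z. The full heterogeneity curve is
    returned for plotting and audit.
    """
    if len(scans) == 0:
        raise ValueError("no scans supplied")
    if len(scans) < 2:
        raise ValueError("need at least two slices to choose a distance")
    z = np.array([s.z_mm for s in scans], dtype=float)
    if np.unique(z).size != z.size:
        raise ValueError("slice z values must be distinct")
    order = np.argsort(z)
    if mask_radius_mm is None:
        mask_radius_mm = DEFAULT_MASK_RADIUS_MM
    het = np.array([heterogeneity(scans[i], mask_radius_mm) for i in order])
    zs = z[order]
    i_best = int(np.argmin(het))  # argmin takes the first (= smallest z) on ties
    curve = HeterogeneityCurve(zs, het, mask_radius_mm)
    return OptimalDistanceResult(float(zs[i_best]), float(het[i_best]), curve)


def calibration_point(
    scan: PlanarScan, target_rel_intensity: float = 0.9
) -> tuple[float, float, float]:
    """Grid point whose relative intensity is closest to the target.

    Relative intensity is (pressure / max pressure)^2. Ties are broken by
    smaller radial distance from the axis, then smaller x, then smaller y.
    Returns ``(x_mm, y_mm, achieved_relative_intensity)``.
    """
    if scan.pressure.size == 0 or scan.pressure.max() <= 0:
        raise DegenerateDataError("calibration point undefined for an all-zero scan")
    rel = scan.relative_intensity()
    xg, yg = np.meshgrid(scan.x_mm, scan.y_mm, indexing="ij")
    score = np.abs(rel - target_rel_intensity)
    keys = np.lexsort(
        (yg.ravel(), xg.ravel(), (xg**2 + yg**2).ravel(), score.ravel())
    )
    i = keys[0]
    return (float(xg.ravel()[i]), float(yg.ravel()[i]), float(rel.ravel()[i]))


def crosstalk_db(scan: PlanarScan, lateral_offset_mm: float) -> float:
    """Worst-case intensity leak beyond a radial offset, in dB.

    Returns ``10 log10(I(offset) / I_max)`` where I is pressure squared and
    I(offset) is the maximum intensity at radial distance >= the offset from
    the acoustic axis. Always <= 0; ``-inf`` if the annulus is silent.
    """
    xg, yg = np.meshgrid(scan.x_mm, scan.y_mm, indexing="ij")
    r = np.hypot(xg, yg)
    if lateral_offset_mm < 0 or lateral_offset_mm > r.max():
        raise ValueError("lateral offset outside the scan extent")
    intensity = scan.pressure**2
    i_max = intensity.max()
    if i_max <= 0:
        raise DegenerateDataError("cross-talk undefined for an all-zero scan")
    i_off = intensity[r >= lateral_offset_mm].max()
    if i_off <= 0:
        return float("-inf")
    return float(10.0 * np.log10(i_off / i_max))


def crosstalk_contours(
    scan: PlanarScan, levels_db: Sequence[float] = (-6.0, -18.0)
) -> dict[float, list[np.ndarray]]:
    """Iso-level contour polygons of the dB intensity map, in mm coordinates.

    Used for the reporting overlay (solid -6 dB and dashed -18 dB contours
    around the source footprint). Each polygon is an (N, 2) array of
    (x_mm, y_mm) vertices.
    """
    intensity = scan.pressure**2
    i_max = intensity.max()
    if i_max <= 0:
        raise DegenerateDataError("contours undefined for an all-zero scan")
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(intensity / i_max)
    dx = scan.spacing_mm
    out: dict[float, list[np.ndarray]] = {}
    for level in levels_db:
        polys = []
        for c in measure.find_contours(db, level):
            xy = np.column_stack(
                [scan.x_mm[0] + c[:, 0] * dx, scan.y_mm[0] + c[:, 1] * dx]
            )
            polys.append(xy)
        out[float(level)] = polys
    return out


def plan_treatment(
    scans: Sequence[PlanarScan],
    wide_scan: PlanarScan | None = None,
    mask_radius_mm: float | None = None,
    target_rel_intensity: float = 0.9,
    neighbor_offset_mm: float = NEIGHBOR_EDGE_OFFSET_MM,
) -> TreatmentPlan:
    """Run the full characterization pipeline for one transducer.

    Chooses the optimal treatment distance from the candidate slices, picks
    the ~90% relative-intensity calibration point on the optimal slice and,
    if a wide scan of the optimal plane is supplied, evaluates the
    cross-talk at the neighbouring-crystal edge offset.
    """
    res = optimal_distance(scans, mask_radius_mm)
    best = min(scans, key=lambda s: abs(s.z_mm - res.optimal_z_mm))
    calib = calibration_point(best, target_rel_intensity)
    xtalk = None
    if wide_scan is not None:
        xtalk = crosstalk_db(wide_scan, neighbor_offset_mm)
    return TreatmentPlan(
        optimal_z_mm=res.optimal_z_mm,
        heterogeneity_at_optimum=res.heterogeneity_at_optimum,
        calibration_point=calib,
        crosstalk_db_at_neighbor=xtalk,
        curve=res.curve,
    )
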