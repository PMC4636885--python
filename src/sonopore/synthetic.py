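"""Seeded generators for every input the analysis pipeline consumes.

Four generators, each a pure function of its parameters and seed:

* noisy planar "hydrophone" scans of a simulated piston field,
* three-channel fluorescence fields of view with per-cell ground truth,
* before/after detachment dot images with a known loss fraction,
* replicate response tables with prescribed per-group means and SDs,
  including presets carrying the study's reported group statistics.

Defaults mirror the study conditions: 20-mm 1-MHz piston scanned at 0.7 mm
pitch; 12-bit micrographs whose positive cells carry an elevated mean
channel intensity over a noisy background; 3 treatments x 3 temperatures
x 3 replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import CapacityError
from .fluorescence import FieldOfViewImages
from .piston_field import PistonTransducer, PlanarScan, field_on_plane
from .stats import TEMPERATURES, TREATMENTS

__all__ = [
    "FovGroundTruth",
    "GroupSpec",
    "GROUP_PRESETS",
    "generate_scan_set",
    "generate_fov",
    "generate_dot_images",
    "generate_experiment",
]


def generate_scan_set(
    tx: PistonTransducer,
    z_list_mm: Sequence[float],
    spacing_mm: float = 0.7,
    half_width_mm: float = 5.25,
    noise_sd: float = 0.0,
    seed: int | None = None,
    base_scans: Sequence[PlanarScan] | None = None,
) -> list[PlanarScan]:
    """Simulated hydrophone scans with additive Gaussian amplitude noise.

    Noise is zero-mean with standard deviation ``noise_sd`` (same relative
    units as the field); noisy amplitudes are clipped at zero, as a
    hydrophone reports magnitudes. With ``noise_sd = 0`` the output is
    bit-identical to :func:`~sonopore.piston_field.field_on_plane`.
    ``base_scans`` lets a caller reuse precomputed noise-free slices when
    drawing many noisy realizations of the same geometry.
    """
    if base_scans is None:
        base_scans = [
            field_on_plane(tx, z, half_width_mm, spacing_mm) for z in z_list_mm
        ]
    else:
        if [s.z_mm for s in base_scans] != [float(z) for z in z_list_mm]:
            raise ValueError("base_scans do not match the requested z list")
    if noise_sd == 0:
        return list(base_scans)
    rng = np.random.default_rng(seed)
    out = []
    for s in base_scans:
        noisy = np.clip(s.pressure + rng.normal(0.0, noise_sd, s.pressure.shape), 0, None)
        out.append(
            PlanarScan(s.z_mm, s.x_mm.copy(), s.y_mm.copy(), noisy, "simulated")
        )
    return out


@dataclass
class FovGroundTruth:
    """Per-cell ground truth behind one generated field of view."""

    centers_px: np.ndarray  # (N, 2) row, col
    nucleus_radii_px: np.ndarray
    cytoplasm_radii_px: np.ndarray
    transfected: np.ndarray  # bool per cell
    apoptotic: np.ndarray  # bool per cell
    params: dict = field(default_factory=dict)
    seed: int | None = None

    @property
    def n_cells(self) -> int:
        return len(self.centers_px)

    @property
    def transfected_fraction(self) -> float:
        return float(self.transfected.mean()) if self.n_cells else 0.0

    @property
    def apoptotic_fraction(self) -> float:
        return float(self.apoptotic.mean()) if self.n_cells else 0.0


def _disk_mask(shape, center, radius):
    r0, c0 = center
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2


def _assign_flags(rng, n_cells: int, fraction: float) -> np.ndarray:
    """Deterministically sized positive set: round(fraction*n) cells after a
    seeded shuffle, so requested fractions are met exactly when integral."""
    k = int(round(fraction * n_cells))
    flags = np.zeros(n_cells, dtype=bool)
    flags[rng.permutation(n_cells)[:k]] = True
    return flags


def generate_fov(
    n_cells: int = 100,
    shape: tuple[int, int] = (512, 512),
    transfected_fraction: float = 0.05,
    apoptotic_fraction: float = 0.01,
    background_mean: float = 100.0,
    background_sd: float = 8.0,
    nucleus_intensity: float = 1200.0,
    signal_offset: float = 400.0,
    cell_shading: float = 6.0,
    nucleus_radius_px: tuple[float, float] = (6.0, 9.0),
    cytoplasm_extra_px: tuple[float, float] = (7.0, 11.0),
    seed: int | None = None,
    max_attempts: int = 10_000,
) -> tuple[FieldOfViewImages, FovGroundTruth]:
    """Generate one three-channel FOV with known per-cell ground truth.

    Nuclei are bright disks in blue; a transfected cell adds
    ``signal_offset`` over its whole cell disk (cytoplasm and nucleus) in
    green; an apoptotic cell adds the offset over its nucleus in red. All
    channels carry Gaussian background noise of sd ``background_sd`` and a
    small negative ``cell_shading`` offset over each cell footprint in the
    antibody channels (cells displace the faintly fluorescent medium), so
    that a negative cell's mean sits strictly below the background mean
    even in the noiseless limit. Values are rounded and clipped to the
    12-bit range. Cells are placed by rejection sampling with no overlap.

    Raises
    ------
    CapacityError
        If the requested cells cannot be placed within ``max_attempts``.
    """
    rng = np.random.default_rng(seed)
    nuc_r = rng.uniform(*nucleus_radius_px, size=n_cells)
    cyt_r = nuc_r + rng.uniform(*cytoplasm_extra_px, size=n_cells)
    margin = cyt_r.max() + 2 if n_cells else 0
    centers = np.empty((n_cells, 2))
    placed = 0
    attempts = 0
    while placed < n_cells:
        if attempts >= max_attempts:
            raise CapacityError(
                f"could not place {n_cells} non-overlapping cells in "
                f"{max_attempts} attempts"
            )
        attempts += 1
        cand = rng.uniform([margin, margin], [shape[0] - margin, shape[1] - margin])
        d = np.linalg.norm(centers[:placed] - cand, axis=1) if placed else np.array([])
        if placed == 0 or np.all(d > cyt_r[:placed] + cyt_r[placed] + 3):
            centers[placed] = cand
            placed += 1
    transfected = _assign_flags(rng, n_cells, transfected_fraction)
    apoptotic = _assign_flags(rng, n_cells, apoptotic_fraction)

    def _noise():
        if background_sd == 0:
            return np.full(shape, background_mean)
        return background_mean + rng.normal(0.0, background_sd, shape)

    blue, green, red = _noise(), _noise(), _noise()
    for i in range(n_cells):
        nuc = _disk_mask(shape, centers[i], nuc_r[i])
        cell = _disk_mask(shape, centers[i], cyt_r[i])
        blue[nuc] += nucleus_intensity
        green[cell] -= cell_shading
        red[cell] -= cell_shading
        if transfected[i]:
            green[cell] += signal_offset
        if apoptotic[i]:
            red[nuc] += signal_offset
    imgs = FieldOfViewImages(
        *(np.clip(np.rint(ch), 0, 4095).astype(np.uint16) for ch in (blue, green, red))
    )
    truth = FovGroundTruth(
        centers_px=centers,
        nucleus_radii_px=nuc_r,
        cytoplasm_radii_px=cyt_r,
        transfected=transfected,
        apoptotic=apoptotic,
        params={
            "n_cells": n_cells,
            "shape": shape,
            "transfected_fraction": transfected_fraction,
            "apoptotic_fraction": apoptotic_fraction,
            "background_mean": background_mean,
            "background_sd": background_sd,
            "nucleus_intensity": nucleus_intensity,
            "signal_offset": signal_offset,
            "cell_shading": cell_shading,
        },
        seed=seed,
    )
    return imgs, truth


def generate_dot_images(
    k_before: int,
    loss_fraction: float,
    seed: int | None = None,
    shape: tuple[int, int] = (512, 512),
    dot_radius_px: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Before/after marker-dot images with a known loss fraction.

    The before image holds ``k_before`` disjoint dots; the after image keeps
    ``round((1 - loss_fraction) * k_before)`` of them (a seeded random
    subset), so :func:`~sonopore.detachment.cell_loss` on the pair returns
    exactly ``-100 * loss_fraction`` when the counts are integral.
    """
    if not (0.0 <= loss_fraction <= 1.0):
        raise ValueError("loss_fraction must be in [0, 1]")
    if k_before < 0:
        raise ValueError("k_before must be nonnegative")
    rng = np.random.default_rng(seed)
    margin = dot_radius_px + 2
    centers = np.empty((k_before, 2))
    placed = 0
    attempts = 0
    while placed < k_before:
        if attempts >= 100 * max(k_before, 1):
            raise CapacityError("could not place the requested number of dots")
        attempts += 1
        cand = rng.uniform([margin, margin], [shape[0] - margin, shape[1] - margin])
        d = np.linalg.norm(centers[:placed] - cand, axis=1) if placed else np.array([])
        if placed == 0 or np.all(d > 2 * dot_radius_px + 3):
            centers[placed] = cand
            placed += 1
    before = np.zeros(shape, dtype=np.uint16)
    for c in centers:
        before[_disk_mask(shape, c, dot_radius_px)] = 4095
    k_after = int(round((1.0 - loss_fraction) * k_before))
    keep = rng.permutation(k_before)[:k_after]
    after = np.zeros(shape, dtype=np.uint16)
    for c in centers[keep]:
        after[_disk_mask(shape, c, dot_radius_px)] = 4095
    return before, after


@dataclass
class GroupSpec:
    """Mean and SD of the response for each of the nine design cells."""

    cells: dict  # (treatment, temperature) -> (mean, sd)
    n_replicates: int = 3

    def __post_init__(self) -> None:
        expected = {(t, c) for t in TREATMENTS for c in TEMPERATURES}
        if set(self.cells) != expected:
            raise ValueError("GroupSpec must cover all 9 treatment x temperature cells")
        if any(sd < 0 for _, sd in self.cells.values()):
            raise ValueError("SDs must be nonnegative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def _preset(rows) -> GroupSpec:
    cells = {}
    for treatment, stats in rows.items():
        for temp, (mean, sd) in zip(TEMPERATURES, stats):
            cells[(treatment, temp)] = (mean, sd)
    return GroupSpec(cells=cells)


#: Reported per-group response statistics (mean, SD) at 37, 39.5, 42 degC:
#: transfected cells (%), relative cell loss (%), apoptotic cells (%).
GROUP_PRESETS: dict[str, GroupSpec] = {
    "transfection": _preset(
        {
            "US+UCA": [(5.4, 0.92), (5.8, 1.3), (5.3, 1.1)],
            "US": [(0.66, 0.38), (1.1, 0.46), (0.57, 0.26)],
            "UCA": [(0.50, 0.22), (0.73, 0.24), (1.3, 0.53)],
        }
    ),
    "cell_loss": _preset(
        {
            "US+UCA": [(-31.0, 3.4), (-32.0, 13.0), (-34.0, 17.0)],
            "US": [(-6.7, 7.9), (-9.1, 8.3), (-18.0, 5.9)],
            "UCA": [(-5.6, 7.4), (-2.8, 7.9), (-2.2, 12.2)],
        }
    ),
    "apoptosis": _preset(
        {
            "US+UCA": [(0.34, 0.15), (0.22, 0.08), (0.41, 0.2)],
            "US": [(0.31, 0.25), (0.22, 0.10), (0.23, 0.11)],
            "UCA": [(0.18, 0.17), (0.32, 0.08), (0.21, 0.10)],
        }
    ),
}


def generate_experiment(spec: GroupSpec | str, seed: int | None = None) -> pd.DataFrame:
    """Replicate response table drawn cell-wise from Normal(mean, sd).

    ``spec`` may be a :class:`GroupSpec` or the name of a preset
    (``"transfection"``, ``"cell_loss"``, ``"apoptosis"``). Returns a tidy
    DataFrame with columns treatment, temperature, replicate, response.
    """
    if isinstance(spec, str):
        spec = GROUP_PRESETS[spec]
    rng = np.random.default_rng(seed)
    rows = []
    for treatment in TREATMENTS:
        for temp in TEMPERATURES:
            mean, sd = spec.cells[(treatment, temp)]
            draws = mean + sd * rng.standard_normal(spec.n_replicates)
            for r, value in enumerate(draws, start=1):
                rows.append((treatment, temp, r, float(value)))
    return pd.DataFrame(
        rows, columns=["treatment", "temperature", "replicate", "response"]
    )
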