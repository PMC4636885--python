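"""Fluorescence-micrograph segmentation and positivity scoring.

Each field of view (FOV) is a three-channel 12-bit micrograph: blue (DAPI,
nuclei), green (GFP secondary antibody, transfection) and red (cleaved-PARP
secondary antibody, apoptosis). Two object sets are segmented: nuclei from
the blue channel, and cell-boundary objects from a combination of blue and
green (GFP signal fills both cytoplasm and nucleus of a transfected cell).
An object is scored positive in a channel when its mean intensity clears
the background by ``n`` background standard deviations:

    I_obj_mean >= I_bg_mean + n * sigma_bg        (inclusive; default n = 3)

Transfection is scored on cell-boundary objects against green; apoptosis on
nuclei against red. Per-FOV positive fractions are averaged per biological
replicate for statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from skimage import measure, segmentation

from .exceptions import DegenerateDataError

__all__ = [
    "FieldOfViewImages",
    "ObjectSet",
    "FovQuantification",
    "ReplicateSummary",
    "otsu_threshold",
    "segment_nuclei",
    "segment_cell_boundaries",
    "classify_positive",
    "quantify_fov",
    "replicate_average",
]

DEFAULT_MIN_OBJECT_AREA = 30  # px; suppresses noise specks
CHANNELS = ("blue", "green", "red")


@dataclass
class FieldOfViewImages:
    """One field of view: blue/green/red rasters of identical shape.

    Values must lie in the declared camera bit range (12-bit by default,
    i.e. 0..4095).
    """

    blue: np.ndarray
    green: np.ndarray
    red: np.ndarray
    bit_depth: int = 12
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.blue = np.asarray(self.blue)
        self.green = np.asarray(self.green)
        self.red = np.asarray(self.red)
        if not (self.blue.shape == self.green.shape == self.red.shape):
            raise ValueError("channel rasters must have identical shapes")
        if self.blue.ndim != 2:
            raise ValueError("channel rasters must be 2-D")
        top = 2**self.bit_depth - 1
        for name in CHANNELS:
            ch = getattr(self, name)
            if ch.min() < 0 or ch.max() > top:
                raise ValueError(
                    f"{name} channel values outside the {self.bit_depth}-bit "
                    f"range [0, {top}]"
                )

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise ValueError(f"unknown channel {name!r}")
        return getattr(self, name)

    @classmethod
    def from_files(cls, blue_path, green_path, red_path, **kwargs):
        import imageio.v3 as iio

        return cls(
            blue=iio.imread(blue_path),
            green=iio.imread(green_path),
            red=iio.imread(red_path),
            **kwargs,
        )

    def to_files(self, blue_path, green_path, red_path) -> None:
        import tifffile

        for path, name in ((blue_path, "blue"), (green_path, "green"), (red_path, "red")):
            tifffile.imwrite(str(path), self.channel(name).astype(np.uint16))


def otsu_threshold(raster: np.ndarray) -> float:
    """Otsu's global threshold: maximize between-class weighted variance.

    Exhaustively evaluates every split between consecutive unique values and
    returns the midpoint of the best split (foreground = pixels strictly
    above the returned threshold). Equivalent to minimizing intra-class
    weighted variance. Ties go to the lowest threshold. Deterministic.

    Raises
    ------
    DegenerateDataError
        If the raster has fewer than two distinct values.
    """
    values, counts = np.unique(np.asarray(raster).ravel(), return_counts=True)
    if values.size < 2:
        raise DegenerateDataError("constant raster has no histogram split")
    values = values.astype(float)
    w0 = np.cumsum(counts)[:-1]
    s0 = np.cumsum(values * counts)[:-1]
    n = counts.sum()
    total = (values * counts).sum()
    w1 = n - w0
    mu0 = s0 / w0
    mu1 = (total - s0) / w1
    between = w0 * w1 * (mu0 - mu1) ** 2
    i = int(np.argmax(between))  # first max on ties -> lowest threshold
    return float(0.5 * (values[i] + values[i + 1]))


@dataclass
class ObjectSet:
    """Labelled objects of one kind plus per-channel intensity statistics.

    ``label_raster`` holds 0 for background and 1..N for objects. Per-object
    channel means and the background mean/std (over label-0 pixels only) are
    computed at construction from the parent FOV.
    """

    label_raster: np.ndarray
    kind: str  # "nuclei" | "cell_boundary"
    object_means: dict = field(default_factory=dict)  # channel -> (N,) array
    background_mean: dict = field(default_factory=dict)  # channel -> float
    background_std: dict = field(default_factory=dict)  # channel -> float
    background_n: int = 0

    @property
    def n_objects(self) -> int:
        return int(self.label_raster.max())

    @property
    def labels(self) -> np.ndarray:
        return np.arange(1, self.n_objects + 1)

    def centroids(self) -> np.ndarray:
        """(N, 2) array of object centroids in (row, col) pixels."""
        return np.array(
            ndimage.center_of_mass(
                np.ones_like(self.label_raster), self.label_raster, self.labels
            )
        ).reshape(-1, 2)

    def areas(self) -> np.ndarray:
        return np.bincount(self.label_raster.ravel())[1:]

    @classmethod
    def from_labels(
        cls, label_raster: np.ndarray, fov: FieldOfViewImages, kind: str
    ) -> "ObjectSet":
        label_raster = np.asarray(label_raster)
        n = int(label_raster.max())
        bg = label_raster == 0
        obj = cls(label_raster=label_raster, kind=kind, background_n=int(bg.sum()))
        idx = np.arange(1, n + 1)
        for name in CHANNELS:
            ch = fov.channel(name).astype(float)
            obj.object_means[name] = (
                ndimage.mean(ch, label_raster, idx) if n else np.empty(0)
            )
            if obj.background_n:
                obj.background_mean[name] = float(ch[bg].mean())
                obj.background_std[name] = float(ch[bg].std())  # population std
        return obj


def _relabel_sequential(labels: np.ndarray) -> np.ndarray:
    out, _, _ = segmentation.relabel_sequential(labels)
    return out


def segment_nuclei(
    fov: FieldOfViewImages, min_object_area: int = DEFAULT_MIN_OBJECT_AREA
) -> ObjectSet:
    """Nuclei objects from the blue (DAPI) channel.

    Otsu threshold -> 8-connected components -> components smaller than
    ``min_object_area`` pixels removed -> labels renumbered 1..N.
    """
    thr = otsu_threshold(fov.blue)
    mask = fov.blue > thr
    labels = measure.label(mask, connectivity=2)
    if labels.max():
        sizes = np.bincount(labels.ravel())
        kill = np.flatnonzero(sizes < min_object_area)
        labels[np.isin(labels, kill)] = 0
        labels = _relabel_sequential(labels)
    return ObjectSet.from_labels(labels, fov, "nuclei")


def _minmax_norm(img: np.ndarray) -> np.ndarray:
    img = img.astype(float)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def segment_cell_boundaries(
    fov: FieldOfViewImages,
    nuclei: ObjectSet | None = None,
    min_object_area: int = DEFAULT_MIN_OBJECT_AREA,
) -> ObjectSet:
    """Cell-boundary objects from the blue and green channels combined.

    The combined image is the pixelwise maximum of the min-max-normalized
    blue and green channels (max keeps GFP-negative cells visible through
    their nuclei). It is Otsu-thresholded and the foreground is split by a
    nuclei-seeded watershed, yielding exactly one cell object per nucleus,
    each a superset of its nucleus. With an empty green channel the result
    degenerates to the nuclei objects.
    """
    if nuclei is None:
        nuclei = segment_nuclei(fov, min_object_area)
    if nuclei.n_objects == 0:
        return ObjectSet.from_labels(
            np.zeros_like(fov.blue, dtype=int), fov, "cell_boundary"
        )
    combined = np.maximum(_minmax_norm(fov.blue), _minmax_norm(fov.green))
    thr = otsu_threshold(combined)
    fg = combined > thr
    fg |= nuclei.label_raster > 0  # every nucleus belongs to its cell
    labels = segmentation.watershed(
        -combined, markers=nuclei.label_raster, mask=fg, connectivity=2
    )
    return ObjectSet.from_labels(labels, fov, "cell_boundary")


def classify_positive(
    objects: ObjectSet, channel: str, n: float = 3.0
) -> np.ndarray:
    """Positivity per object: mean intensity >= bg mean + n * bg std.

    The inequality is inclusive, so at n = 0 an object exactly at the
    background mean is positive. Decisions are invariant under any common
    affine rescaling I -> a*I + b (a > 0) of the channel.
    """
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}")
    if objects.background_n < 2:
        raise DegenerateDataError(
            "background must contain at least two pixels to define its statistics"
        )
    thr = objects.background_mean[channel] + n * objects.background_std[channel]
    return objects.object_means[channel] >= thr


@dataclass
class FovQuantification:
    """Counts and fractions for one field of view.

    Fractions are ``None`` (missing, not zero) when the FOV holds no cells.
    """

    n_cells: int
    n_transfected: int
    n_apoptotic: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_transfected <= self.n_cells):
            raise ValueError("transfected count must lie in [0, n_cells]")
        if not (0 <= self.n_apoptotic <= self.n_cells):
            raise ValueError("apoptotic count must lie in [0, n_cells]")

    @property
    def transfected_fraction(self) -> float | None:
        return None if self.n_cells == 0 else self.n_transfected / self.n_cells

    @property
    def apoptotic_fraction(self) -> float | None:
        return None if self.n_cells == 0 else self.n_apoptotic / self.n_cells


def quantify_fov(
    fov: FieldOfViewImages,
    n: float = 3.0,
    min_object_area: int = DEFAULT_MIN_OBJECT_AREA,
) -> FovQuantification:
    """Segment one FOV and score transfection and apoptosis.

    Transfection is scored on cell-boundary objects against the green
    channel; apoptosis on nuclei objects against the red channel; both with
    the ``n``-sigma background criterion.
    """
    nuclei = segment_nuclei(fov, min_object_area)
    cells = segment_cell_boundaries(fov, nuclei, min_object_area)
    if cells.n_objects == 0:
        return FovQuantification(0, 0, 0)
    transfected = classify_positive(cells, "green", n)
    apoptotic = classify_positive(nuclei, "red", n)
    return FovQuantification(
        n_cells=cells.n_objects,
        n_transfected=int(transfected.sum()),
        n_apoptotic=int(apoptotic.sum()),
    )


@dataclass
class ReplicateSummary:
    """Unweighted per-replicate mean of per-FOV positive fractions."""

    n_fov: int
    transfected_fraction: float
    apoptotic_fraction: float


def replicate_average(fov_results: Sequence[FovQuantification]) -> ReplicateSummary:
    """Average per-FOV fractions within one biological replicate.

    The mean is unweighted over fields of view (not pooled counts); FOVs
    with zero cells are excluded. Raises if every FOV is empty.
    """
    usable = [r for r in fov_results if r.n_cells > 0]
    if not usable:
        raise DegenerateDataError("no field of view contains any cells")
    return ReplicateSummary(
        n_fov=len(usable),
        transfected_fraction=float(
            np.mean([r.transfected_fraction for r in usable])
        ),
        apoptotic_fraction=float(np.mean([r.apoptotic_fraction for r in usable])),
    )
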