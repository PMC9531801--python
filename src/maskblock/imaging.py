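"""Quantification of scanned stain patterns.

A spray experiment leaves blue stains on a white screen; the screen is
scanned, binarized, and summarised by the mean stain-pixel fraction.  The
Ballistic Blocking Capacity of a cloth compares that fraction with and
without the obstacle:

    BBC = (1 - <p_o> / <p_no>) * 100 %

where ``<p_o>`` and ``<p_no>`` are the mean binary pixel values, each
averaged over the replicate images of its configuration.  BBC = 100 % when
the obstacle stopped every droplet and 0 % when the stain density is
unchanged.  Individual stains are additionally detected as connected
components and characterised by the diameter of the disk with the same area.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage import measure
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

__all__ = [
    "ScanImage",
    "BinarizationPolicy",
    "Stain",
    "StainPattern",
    "StainSummary",
    "BBCResult",
    "load_scan",
    "read_manifest",
    "binarize",
    "mean_pixel_fraction",
    "detect_stains",
    "stain_statistics",
    "compute_bbc",
    "propagate_bbc_uncertainty",
]

UM_PER_INCH = 25400.0


@dataclass(frozen=True)
class ScanImage:
    """A grayscale scan with its physical resolution and provenance."""

    pixels: np.ndarray  # 2-D grayscale intensities
    dpi: float
    configuration: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        if not self.dpi > 0:
            raise ValueError("dpi must be positive")
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D grayscale grid")

    @property
    def um_per_pixel(self) -> float:
        return UM_PER_INCH / self.dpi


@dataclass(frozen=True)
class BinarizationPolicy:
    """How raw intensities become a stain mask.

    ``method`` is "otsu" (parameter-free, the default) or "fixed" (use
    ``threshold``).  ``stains_dark`` states the scan's ink polarity: True if
    stains are darker than the background (as for blue stains scanned on a
    white screen).  Either polarity maps stains to 1.
    """

    method: str = "otsu"
    threshold: Optional[float] = None
    stains_dark: bool = True

    def __post_init__(self) -> None:
        if self.method not in ("otsu", "fixed"):
            raise ValueError("method must be 'otsu' or 'fixed'")
        if self.method == "fixed" and self.threshold is None:
            raise ValueError("fixed-threshold policy requires a threshold value")


def load_scan(path, dpi: float, configuration: str = "", replicate: str = "") -> ScanImage:
    """Load a PNG/TIFF scan as grayscale.  RGB(A) input is luma-averaged."""
    px = np.asarray(iio.imread(path))
    if px.ndim == 3:
        px = px[..., :3].mean(axis=-1)
    return ScanImage(pixels=px.astype(float), dpi=dpi, configuration=configuration, replicate=str(replicate))


def read_manifest(path) -> list[ScanImage]:
    """Load every image listed in a manifest CSV (path, configuration, replicate, dpi).

    Relative image paths are resolved against the manifest's directory.
    """
    path = Path(path)
    table = pd.read_csv(path)
    required = {"path", "configuration", "replicate", "dpi"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    scans = []
    for row in table.itertuples(index=False):
        img_path = Path(row.path)
        if not img_path.is_absolute():
            img_path = path.parent / img_path
        scans.append(load_scan(img_path, dpi=float(row.dpi), configuration=str(row.configuration), replicate=str(row.replicate)))
    return scans


def binarize(image: ScanImage, policy: BinarizationPolicy = BinarizationPolicy()) -> np.ndarray:
    """Map a grayscale scan to a boolean stain mask (stain = True).

    A uniform image gives Otsu nothing to separate; it is treated as
    stain-free (all False) with a logged warning.
    """
    px = np.asarray(image.pixels, dtype=float)
    if policy.method == "fixed":
        thr = float(policy.threshold)
    else:
        if np.ptp(px) == 0:
            logger.warning(
                "uniform image (configuration=%r replicate=%r): Otsu undefined, assuming no stains",
                image.configuration,
                image.replicate,
            )
            return np.zeros(px.shape, dtype=bool)
        thr = threshold_otsu(px)
    return px < thr if policy.stains_dark else px > thr


def mean_pixel_fraction(binary: np.ndarray, roi: Optional[tuple[slice, slice]] = None) -> float:
    """Arithmetic mean of a binary stain mask, optionally inside a row/col slice ROI."""
    grid = np.asarray(binary)
    if roi is not None:
        grid = grid[roi]
    if grid.size == 0:
        raise ValueError("empty region of interest")
    return float(grid.mean())


@dataclass(frozen=True)
class Stain:
    centroid_row_px: float
    centroid_col_px: float
    area_px2: int
    equivalent_diameter_um: float


@dataclass(frozen=True)
class StainPattern:
    """Detected stains of one scan, with equivalent-disk diameters in um."""

    stains: tuple[Stain, ...]
    dpi: float

    def __len__(self) -> int:
        return len(self.stains)

    @property
    def diameters_um(self) -> np.ndarray:
        return np.array([s.equivalent_diameter_um for s in self.stains])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "centroid_x_px": [s.centroid_col_px for s in self.stains],
                "centroid_y_px": [s.centroid_row_px for s in self.stains],
                "area_px2": [s.area_px2 for s in self.stains],
                "eq_diameter_um": [s.equivalent_diameter_um for s in self.stains],
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def detect_stains(binary: np.ndarray, dpi: float, min_area: int = 3) -> StainPattern:
    """Connected-component stains (8-connectivity) with area >= ``min_area`` px.

    Each stain is treated as a disk of the same area: its equivalent diameter
    is ``2 sqrt(A_physical / pi)`` with the physical area from the dpi scale.
    The default ``min_area`` of 3 pixels rejects isolated scanner noise.
    """
    if not dpi > 0:
        raise ValueError("dpi must be positive")
    labels = measure.label(np.asarray(binary, dtype=bool), connectivity=2)
    um_per_px = UM_PER_INCH / dpi
    stains = []
    for region in measure.regionprops(labels):
        if region.area < min_area:
            continue
        area_um2 = region.area * um_per_px**2
        stains.append(
            Stain(
                centroid_row_px=float(region.centroid[0]),
                centroid_col_px=float(region.centroid[1]),
                area_px2=int(region.area),
                equivalent_diameter_um=2.0 * math.sqrt(area_um2 / math.pi),
            )
        )
    return StainPattern(stains=tuple(stains), dpi=dpi)


@dataclass(frozen=True)
class StainSummary:
    count: int
    mean_um: Optional[float]
    sd_um: Optional[float]
    min_um: Optional[float]
    max_um: Optional[float]


def stain_statistics(pattern: StainPattern, ddof: int = 0) -> StainSummary:
    """Mean, SD, min, max and count of equivalent diameters.

    The SD uses the population divisor n by default (``ddof=0``); pass
    ``ddof=1`` for the sample convention.  An empty pattern yields an empty
    summary.
    """
    d = pattern.diameters_um
    if d.size == 0:
        return StainSummary(count=0, mean_um=None, sd_um=None, min_um=None, max_um=None)
    return StainSummary(
        count=int(d.size),
        mean_um=float(d.mean()),
        sd_um=float(d.std(ddof=ddof)) if d.size > ddof else None,
        min_um=float(d.min()),
        max_um=float(d.max()),
    )


@dataclass(frozen=True)
class BBCResult:
    """Ballistic Blocking Capacity of an obstacle configuration."""

    mean_pixel_obstacle: float
    mean_pixel_no_obstacle: float
    bbc: float  # percent; <= 100, may be negative
    sigma: Optional[float]  # percent; None with fewer than 2 replicates per group
    n_obstacle: int
    n_reference: int
    obstacle_fractions: tuple[float, ...] = field(default=())
    reference_fractions: tuple[float, ...] = field(default=())


def propagate_bbc_uncertainty(
    obstacle_fractions: Sequence[float], reference_fractions: Sequence[float]
) -> Optional[float]:
    """First-order uncertainty of BBC from replicate scatter, in percent.

    With m = group means, s = replicate SDs (sample convention) and n =
    replicate counts,

        sigma_BBC = 100 (m_o / m_no) sqrt( (s_o / m_o / sqrt(n_o))^2
                                         + (s_no / m_no / sqrt(n_no))^2 )

    evaluated in a form that stays finite at m_o = 0 (the obstacle term is
    then s_o-driven only).  Returns None when either group has fewer than 2
    replicates.
    """
    po = np.asarray(obstacle_fractions, dtype=float)
    pno = np.asarray(reference_fractions, dtype=float)
    if po.size < 2 or pno.size < 2:
        return None
    m_o, m_no = po.mean(), pno.mean()
    if not m_no > 0:
        raise ValueError("reference mean pixel fraction must be positive")
    se_o = po.std(ddof=1) / math.sqrt(po.size)
    se_no = pno.std(ddof=1) / math.sqrt(pno.size)
    # == 100*(m_o/m_no)*sqrt((se_o/m_o)^2 + (se_no/m_no)^2), finite at m_o=0
    return 100.0 * math.hypot(se_o / m_no, m_o * se_no / m_no**2)


def compute_bbc(
    obstacle_images: Sequence[ScanImage],
    reference_images: Sequence[ScanImage],
    policy: BinarizationPolicy = BinarizationPolicy(),
) -> BBCResult:
    """Ballistic Blocking Capacity from two image groups.

    Each image is binarized and reduced to its mean stain-pixel fraction;
    fractions are averaged within each group (per image first, then across
    replicates) and combined as ``(1 - <p_o>/<p_no>) * 100``.  Raises if the
    barrier-free reference group contains no stain pixels.
    """
    if len(obstacle_images) == 0 or len(reference_images) == 0:
        raise ValueError("both image groups must be non-empty")
    po = [mean_pixel_fraction(binarize(img, policy)) for img in obstacle_images]
    pno = [mean_pixel_fraction(binarize(img, policy)) for img in reference_images]
    m_o = float(np.mean(po))
    m_no = float(np.mean(pno))
    if not m_no > 0:
        raise ValueError("no droplets detected in the barrier-free reference group")
    bbc = (1.0 - m_o / m_no) * 100.0
    sigma = propagate_bbc_uncertainty(po, pno)
    return BBCResult(
        mean_pixel_obstacle=m_o,
        mean_pixel_no_obstacle=m_no,
        bbc=bbc,
        sigma=sigma,
        n_obstacle=len(po),
        n_reference=len(pno),
        obstacle_fractions=tuple(po),
        reference_fractions=tuple(pno),
    )
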