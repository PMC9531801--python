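"""Scanner-like synthetic stain images with known ground truth.

Every imaging-side operation in this package is testable without the real
deposited scans: the simulator produces droplet impacts, and this module
rasterises them into grayscale "scans" — dark disks on a white background,
optionally with salt-and-pepper specks and a mild blur — together with a
manifest recording exactly what was drawn (disk centres, diameters, seeds,
and area- and volume-based blocking ground truth).

The transport model is planar, so an impact has no transverse coordinate;
for visualisation each stain's horizontal position on the screen is drawn
uniformly across the image width.  That is a rendering convention, not
physics, and it leaves the pixel-fraction statistics unaffected in
expectation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk
from skimage.filters import gaussian

from .imaging import ScanImage
from .physics import FluidEnvironment
from .simulator import Barrier, EmissionModel, ExperimentGeometry, ImpactSet, simulate_experiment

__all__ = [
    "RenderSettings",
    "RenderedScan",
    "GroundTruthManifest",
    "render_scan",
    "generate_experiment_set",
]


@dataclass(frozen=True)
class RenderSettings:
    """Rasterisation parameters for synthetic scans.

    The image is a ``width_cm`` x ``height_cm`` window of the screen centred
    (vertically) on the nozzle height.  The default 4800 dpi makes one pixel
    about 5.3 um, fine enough to represent stains near the 7 um
    detectability floor.  ``spread_factor`` is the stain-to-droplet diameter
    ratio (stains are wider than the droplets that caused them; the default
    1.0 keeps stains as direct droplet proxies).  Salt-and-pepper specks are
    single pixels, removed downstream by any minimum-area filter >= 2 px.
    """

    dpi: float = 4800.0
    width_cm: float = 1.0
    height_cm: float = 1.0
    spread_factor: float = 1.0
    salt_pepper_rate: float = 1e-4
    blur_sigma_px: float = 0.0
    stains_dark: bool = True
    background_level: int = 255
    stain_level: int = 0

    def __post_init__(self) -> None:
        if not self.dpi > 0:
            raise ValueError("dpi must be positive")
        if self.width_cm <= 0 or self.height_cm <= 0:
            raise ValueError("image physical size must be positive")
        if not self.spread_factor >= 1.0:
            raise ValueError("spread_factor must be >= 1")
        if not 0.0 <= self.salt_pepper_rate <= 0.01:
            raise ValueError("salt_pepper_rate must lie in [0, 0.01]")

    @property
    def px_per_m(self) -> float:
        return self.dpi / 0.0254

    @property
    def shape(self) -> tuple[int, int]:
        return (
            max(1, int(round(self.height_cm / 100.0 * self.px_per_m))),
            max(1, int(round(self.width_cm / 100.0 * self.px_per_m))),
        )


@dataclass(frozen=True)
class RenderedScan:
    """A rendered image plus the per-image ground-truth manifest entry."""

    image: ScanImage
    disk_centers_px: tuple[tuple[float, float], ...]  # (row, col)
    disk_diameters_um: tuple[float, ...]
    dropped_out_of_extent: int
    seed: int

    @property
    def total_disk_area_um2(self) -> float:
        return float(sum(math.pi * (d / 2.0) ** 2 for d in self.disk_diameters_um))

    def manifest_entry(self) -> dict:
        return {
            "disk_centers_px": [list(c) for c in self.disk_centers_px],
            "disk_diameters_um": list(self.disk_diameters_um),
            "dropped_out_of_extent": self.dropped_out_of_extent,
            "total_disk_area_um2": self.total_disk_area_um2,
            "seed": self.seed,
        }


def render_scan(
    impacts: ImpactSet,
    settings: RenderSettings = RenderSettings(),
    geometry: ExperimentGeometry = ExperimentGeometry(),
    seed: int = 0,
    configuration: str = "",
    replicate: str = "",
) -> RenderedScan:
    """Rasterise the screen impacts of one simulated experiment.

    Each droplet with fate ``hit_roi`` or ``hit_screen`` becomes a filled
    disk of diameter ``spread_factor * 2 r`` at its impact height, with a
    uniformly drawn transverse position.  Impacts outside the image window
    are dropped and counted.  Noise (salt-and-pepper, then Gaussian blur) is
    applied after rasterisation.  Deterministic given ``seed``.
    """
    n_rows, n_cols = settings.shape
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    img = np.full((n_rows, n_cols), settings.background_level, dtype=float)

    hit = np.isin(impacts.fate, ("hit_roi", "hit_screen"))
    y = impacts.y[hit]
    radii = impacts.radius[hit]
    # physical window: vertical band centred on the nozzle height
    y_top = geometry.nozzle_height + settings.height_cm / 200.0
    rows = (y_top - y) * settings.px_per_m
    cols = rng.uniform(0.0, n_cols, size=y.size)
    disk_r_px = settings.spread_factor * radii * settings.px_per_m

    in_extent = (rows >= 0) & (rows < n_rows)
    dropped = int(np.sum(~in_extent))

    centers, diameters = [], []
    for row, col, r_px, r_m in zip(rows[in_extent], cols[in_extent], disk_r_px[in_extent], radii[in_extent]):
        rr, cc = draw_disk((row, col), max(r_px, 0.5), shape=(n_rows, n_cols))
        img[rr, cc] = settings.stain_level
        centers.append((float(row), float(col)))
        diameters.append(float(settings.spread_factor * 2.0 * r_m * 1e6))

    if settings.salt_pepper_rate > 0:
        flips = rng.uniform(size=img.shape) < settings.salt_pepper_rate
        salt = rng.uniform(size=img.shape) < 0.5
        img[flips & salt] = settings.stain_level
        img[flips & ~salt] = settings.background_level
    if settings.blur_sigma_px > 0:
        img = gaussian(img, sigma=settings.blur_sigma_px, preserve_range=True)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    scan = ScanImage(pixels=img, dpi=settings.dpi, configuration=configuration, replicate=str(replicate))
    return RenderedScan(
        image=scan,
        disk_centers_px=tuple(centers),
        disk_diameters_um=tuple(diameters),
        dropped_out_of_extent=dropped,
        seed=seed,
    )


@dataclass
class GroundTruthManifest:
    """Everything needed to check the analysis pipeline against truth."""

    base_seed: int
    replicates: int
    reference_configuration: str
    images: list[dict] = field(default_factory=list)  # path, configuration, replicate, dpi, entry
    configurations: dict = field(default_factory=dict)  # name -> truth summary

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @staticmethod
    def from_json(path) -> "GroundTruthManifest":
        data = json.loads(Path(path).read_text())
        return GroundTruthManifest(**data)

    def area_blocking_percent(self, configuration: str) -> float:
        """Ground-truth blocking from rendered stain areas, percent."""
        ref = self.configurations[self.reference_configuration]["mean_disk_area_um2"]
        obs = self.configurations[configuration]["mean_disk_area_um2"]
        if not ref > 0:
            raise ValueError("reference configuration rendered no stains")
        return (1.0 - obs / ref) * 100.0

    def volume_blocking_percent(self, configuration: str) -> float:
        """Ground-truth blocking from droplet volumes in the ROI band, percent."""
        ref = self.configurations[self.reference_configuration]["mean_roi_volume_m3"]
        obs = self.configurations[configuration]["mean_roi_volume_m3"]
        if not ref > 0:
            raise ValueError("reference configuration received no ROI volume")
        return (1.0 - obs / ref) * 100.0


def generate_experiment_set(
    model: EmissionModel,
    geometry: ExperimentGeometry,
    configurations: dict[str, Optional[Barrier | Sequence[Barrier]]],
    settings: RenderSettings = RenderSettings(),
    replicates: int = 3,
    out_dir: str | Path = ".",
    base_seed: int = 0,
    reference_configuration: str = "free",
    env: FluidEnvironment = FluidEnvironment(),
    write_images: bool = True,
) -> tuple[GroundTruthManifest, list[RenderedScan]]:
    """Simulate and render a full experiment set with replicates.

    ``configurations`` maps a name to its barrier(s) (``None`` for the
    barrier-free reference, which must be present under
    ``reference_configuration``).  Each (configuration, replicate) pair gets
    its own derived seed for both simulation and rendering.  Writes one PNG
    per image, a ground-truth manifest JSON, and the manifest CSV dialect
    (path, configuration, replicate, dpi) the imaging module reads.
    """
    if reference_configuration not in configurations:
        raise ValueError(f"configurations must include the reference {reference_configuration!r}")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    out_dir = Path(out_dir)
    if write_images:
        out_dir.mkdir(parents=True, exist_ok=True)

    manifest = GroundTruthManifest(
        base_seed=base_seed,
        replicates=replicates,
        reference_configuration=reference_configuration,
    )
    rendered: list[RenderedScan] = []
    rows = []
    child_seeds = np.random.SeedSequence(base_seed).generate_state(2 * replicates * len(configurations))

    for ci, (name, barrier) in enumerate(configurations.items()):
        areas, volumes = [], []
        for rep in range(replicates):
            k = 2 * (ci * replicates + rep)
            sim_seed = int(child_seeds[k] % (2**31))
            render_seed = int(child_seeds[k + 1] % (2**31))
            rep_model = EmissionModel(**{**asdict(model), "seed": sim_seed})
            impacts = simulate_experiment(rep_model, geometry, barrier, env)
            scan = render_scan(
                impacts, settings, geometry, seed=render_seed, configuration=name, replicate=str(rep)
            )
            rendered.append(scan)
            areas.append(scan.total_disk_area_um2)
            volumes.append(impacts.roi_volume())
            fname = f"{name}_rep{rep}.png"
            if write_images:
                iio.imwrite(out_dir / fname, scan.image.pixels)
            rows.append({"path": fname, "configuration": name, "replicate": rep, "dpi": settings.dpi})
            manifest.images.append(
                {"path": fname, "configuration": name, "replicate": rep, "dpi": settings.dpi, **scan.manifest_entry()}
            )
        manifest.configurations[name] = {
            "mean_disk_area_um2": float(np.mean(areas)),
            "mean_roi_volume_m3": float(np.mean(volumes)),
            "barrier": [asdict(b) for b in _as_barrier_list(barrier)],
        }

    if write_images:
        pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
        manifest.to_json(out_dir / "manifest.json")
    return manifest, rendered


def _as_barrier_list(barrier) -> list[Barrier]:
    if barrier is None:
        return []
    if isinstance(barrier, Barrier):
        return [barrier]
    return list(barrier)
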