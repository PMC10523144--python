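"""Synthetic stained-islet images with known ground truth.

Every other module of this package is testable without any microscopy data
because this generator renders islets whose cell placements are known by
construction: a boundary polygon (regular or angle-jittered n-gon, or
explicit vertices) and filled-disc "cell" blobs placed at a chosen fraction
of the boundary radius along a chosen (or random) direction. Blob positions
use the same angular-interpolation boundary radius the analysis measures, so
the intended radius fraction of a blob center is exactly the statistic the
pipeline should recover (up to the spatial extent of the disc).

Three cohort phenotypes mirror the biological regimes of interest:

* ``mantle`` — peripheral cells, radius fractions ~ Uniform(0.85, 0.95),
  the healthy rodent mantle-core arrangement;
* ``core``   — central cells, fractions ~ Uniform(0.2, 0.4), the
  center-shifted arrangement seen under impaired glucose tolerance;
* ``diffuse`` — area-uniform placement, fractions ~ sqrt(Uniform(0, 1)),
  whose expected relative radius on a disc is 2/3.

IHC blobs are colored by sampling HSV triples inside the default brown
detection box (with a safety margin against 8-bit quantization) on an
eosin/hematoxylin-like background chosen outside the box; IF blobs are
bright discs on a dim background. Optional additive Gaussian noise is
clipped to the valid range; its default is 0 so rendered images match the
ground-truth positivity map pixel for pixel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.color import hsv2rgb
from skimage.draw import disk

from .geometry import (
    IsletPolygon,
    boundary_radius_at_angle,
    polygon_centroid,
    validate_polygon,
)

__all__ = [
    "GroundTruth",
    "PhenotypeSpec",
    "Placement",
    "PHENOTYPES",
    "generate_cohort",
    "generate_islet",
    "regular_ngon",
    "perturbed_ngon",
    "sample_fractions",
]

PHENOTYPES = ("mantle", "core", "diffuse")

# eosin/hematoxylin-like pale bluish-gray; hue ~249 deg, saturation ~0.15 —
# outside the default brown box on both axes (heuristic, like the box itself)
IHC_BACKGROUND_RGB = (205, 200, 235)
IF_BACKGROUND = 26    # ~0.10 of the 8-bit range
IF_FOREGROUND = 217   # ~0.85


@dataclass
class Placement:
    """One group of blobs at a fixed radius fraction.

    ``angle=None`` draws a fresh uniform angle per blob.
    """

    radius_fraction: float
    angle: float | None = None
    blob_radius_px: float = 2.0
    count: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.radius_fraction <= 1.0):
            raise ValueError("radius_fraction must lie in [0, 1]")
        if self.count < 1:
            raise ValueError("count must be >= 1")


@dataclass
class PhenotypeSpec:
    """Full description of one synthetic islet image."""

    placements: list[Placement] = field(default_factory=list)
    stain_mode: str = "ihc"
    n_vertices: int = 256
    polygon_radius: float = 80.0
    center: tuple[float, float] = (100.5, 100.5)
    jitter_sd: float = 0.0
    explicit_vertices: np.ndarray | None = None
    image_size: tuple[int, int] = (201, 201)  # (height, width)
    noise_sd: float = 0.0
    seed: int = 0


@dataclass
class GroundTruth:
    """What the generator actually placed, pixel-exact before noise."""

    vertices: np.ndarray
    blobs: pd.DataFrame  # columns: x, y, radius_fraction, angle, blob_radius_px
    positivity_map: np.ndarray
    n_positive: int

    @property
    def mean_fraction(self) -> float:
        return float(self.blobs["radius_fraction"].mean()) if len(self.blobs) else float("nan")


def regular_ngon(n: int, radius: float, center: tuple[float, float]) -> np.ndarray:
    """Vertices of a regular n-gon (counterclockwise in image coordinates)."""
    ang = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    cx, cy = center
    return np.column_stack((cx + radius * np.cos(ang), cy + radius * np.sin(ang)))


def perturbed_ngon(
    n: int,
    radius: float,
    jitter_sd: float,
    center: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """n-gon with per-vertex radial jitter (relative sd), angles kept monotone."""
    ang = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    radii = radius * np.clip(1.0 + rng.normal(0.0, jitter_sd, size=n), 0.2, None)
    cx, cy = center
    return np.column_stack((cx + radii * np.cos(ang), cy + radii * np.sin(ang)))


def _blob_pixels(
    x: float, y: float, blob_radius_px: float, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Raster pixels of a filled disc; continuous coords have pixel centers at +0.5."""
    if blob_radius_px <= 0.5:
        return np.array([int(np.floor(y))]), np.array([int(np.floor(x))])
    return disk((y - 0.5, x - 0.5), blob_radius_px, shape=shape)


def generate_islet(
    spec: PhenotypeSpec, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, dict, GroundTruth]:
    """Render one synthetic islet image.

    Returns ``(image, polygon_file_content, ground_truth)``; the polygon dict
    follows the ``.polygons.json`` sidecar schema with ``image`` left None
    for the caller to fill in. Deterministic for a given spec/seed.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    h, w = spec.image_size
    if spec.explicit_vertices is not None:
        vertices = np.asarray(spec.explicit_vertices, dtype=float)
    elif spec.jitter_sd > 0:
        vertices = perturbed_ngon(
            spec.n_vertices, spec.polygon_radius, spec.jitter_sd, spec.center, rng
        )
    else:
        vertices = regular_ngon(spec.n_vertices, spec.polygon_radius, spec.center)
    poly = IsletPolygon(vertices)
    cntr = polygon_centroid(poly)
    _, vpoly = validate_polygon(poly, cntr)

    pos_map = np.zeros((h, w), dtype=bool)
    blob_rows = []
    blob_pixel_sets = []
    for placement in spec.placements:
        for _ in range(placement.count):
            ang = (
                float(rng.uniform(0.0, 2.0 * np.pi))
                if placement.angle is None
                else float(np.mod(placement.angle, 2.0 * np.pi))
            )
            rb = float(boundary_radius_at_angle(vpoly, cntr, ang))
            bx = cntr.cx + placement.radius_fraction * rb * np.cos(ang)
            by = cntr.cy + placement.radius_fraction * rb * np.sin(ang)
            pad = placement.blob_radius_px
            if not (pad <= bx <= w - pad and pad <= by <= h - pad):
                raise ValueError(
                    f"blob at ({bx:.1f}, {by:.1f}) falls outside the "
                    f"{w}x{h} image bounds"
                )
            rr, cc = _blob_pixels(bx, by, placement.blob_radius_px, (h, w))
            pos_map[rr, cc] = True
            blob_pixel_sets.append((rr, cc))
            blob_rows.append(
                {
                    "x": bx,
                    "y": by,
                    "radius_fraction": placement.radius_fraction,
                    "angle": ang,
                    "blob_radius_px": placement.blob_radius_px,
                }
            )

    if spec.stain_mode == "ihc":
        image = np.empty((h, w, 3), dtype=np.uint8)
        image[:] = IHC_BACKGROUND_RGB
        for rr, cc in blob_pixel_sets:
            # sample a brown strictly inside the default detection box, with
            # margin so 8-bit quantization cannot push it out
            hsv = rng.uniform((10 / 360, 0.40, 0.30), (40 / 360, 0.90, 0.80))
            rgb = np.round(hsv2rgb(hsv.reshape(1, 1, 3))[0, 0] * 255).astype(np.uint8)
            image[rr, cc] = rgb
        if spec.noise_sd > 0:
            noisy = image + rng.normal(0.0, spec.noise_sd * 255.0, image.shape)
            image = np.clip(np.round(noisy), 0, 255).astype(np.uint8)
    elif spec.stain_mode == "if":
        image = np.full((h, w), IF_BACKGROUND, dtype=np.uint8)
        image[pos_map] = IF_FOREGROUND
        if spec.noise_sd > 0:
            noisy = image + rng.normal(0.0, spec.noise_sd * 255.0, image.shape)
            image = np.clip(np.round(noisy), 0, 255).astype(np.uint8)
    else:
        raise ValueError(f"unknown stain_mode {spec.stain_mode!r}")

    truth = GroundTruth(
        vertices=vertices,
        blobs=pd.DataFrame(
            blob_rows, columns=["x", "y", "radius_fraction", "angle", "blob_radius_px"]
        ),
        positivity_map=pos_map,
        n_positive=int(pos_map.sum()),
    )
    polygon_content = {
        "image": None,
        "islets": [{"id": 1, "vertices": vertices.tolist()}],
    }
    return image, polygon_content, truth


def sample_fractions(
    phenotype: str, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Radius fractions for one islet of the given cohort phenotype."""
    if phenotype == "mantle":
        return rng.uniform(0.85, 0.95, size=n)
    if phenotype == "core":
        return rng.uniform(0.2, 0.4, size=n)
    if phenotype == "diffuse":
        # area-uniform on a disc: P(f <= t) = t^2
        return np.sqrt(rng.uniform(0.0, 1.0, size=n))
    raise ValueError(f"unknown phenotype {phenotype!r}; choose from {PHENOTYPES}")


def _support_image(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """DAPI-like support image: dim background with a few bright nuclei blobs."""
    h, w = shape
    img = np.full((h, w), 20, dtype=np.uint8)
    for _ in range(30):
        cy, cx = rng.uniform(10, h - 10), rng.uniform(10, w - 10)
        rr, cc = disk((cy, cx), rng.uniform(2, 4), shape=shape)
        img[rr, cc] = int(rng.integers(120, 200))
    return img


def generate_cohort(
    out_dir: str | Path,
    n_islets: int,
    phenotype: str,
    stain_mode: str = "ihc",
    seed: int = 0,
    n_blobs: int = 40,
    blob_radius_px: float = 2.0,
    n_vertices: int = 256,
    jitter_sd: float = 0.0,
    noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Write a cohort folder: images, polygon sidecars, support/ (IF), truth.csv.

    Returns the truth table, one row per islet, recording the intended mean
    radius fraction and the exact pre-noise positive-pixel count.
    """
    if n_islets < 1:
        raise ValueError("n_islets must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(n_islets):
        fractions = sample_fractions(phenotype, n_blobs, rng)
        spec = PhenotypeSpec(
            placements=[
                Placement(float(f), None, blob_radius_px, 1) for f in fractions
            ],
            stain_mode=stain_mode,
            n_vertices=n_vertices,
            jitter_sd=jitter_sd,
            noise_sd=noise_sd,
            seed=int(rng.integers(2**31)),
        )
        image, polygons, truth = generate_islet(spec)
        name = f"{k:03d}_islet.png"
        iio.imwrite(out_dir / name, image)
        polygons["image"] = name
        with open(out_dir / f"{k:03d}_islet.polygons.json", "w", encoding="utf-8") as fh:
            json.dump(polygons, fh)
        if stain_mode == "if":
            support_dir = out_dir / "support"
            support_dir.mkdir(exist_ok=True)
            iio.imwrite(
                support_dir / f"{k:03d}_dapi.png", _support_image(rng, spec.image_size)
            )
        rows.append(
            {
                "image_id": name,
                "islet_id": 1,
                "phenotype": phenotype,
                "n_blobs": n_blobs,
                "mean_fraction_intended": float(fractions.mean()),
                "n_positive_truth": truth.n_positive,
            }
        )
    truth_df = pd.DataFrame(rows)
    truth_df.to_csv(out_dir / "truth.csv", index=False)
    return truth_df
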