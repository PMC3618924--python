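"""Synthetic mammographic image and patch generation.

Real screening archives provide density-graded mammograms with radiologist
chain-code outlines of masses.  This module emulates that data at desk scale
so every downstream stage (ROI extraction, ICA features, classification,
density-stratified evaluation) is exercisable without the archive.

Background model: a *clustered lumpy* texture — Gaussian blobs at
Poisson-distributed locations, with per-density blob rate, amplitude and
scale, plus white noise.  The four BI-RADS density grades (1 = mainly fatty
… 4 = extremely dense) map to non-decreasing blob rate and amplitude, so
denser grades contain more structured bright texture that masks lesions.

Masses are additive radially-decaying bright lesions with irregular margins
(low-order random Fourier perturbation of a circle).  Each inserted mass is
traced into a closed 8-connected chain-code boundary in the same overlay
dialect the ROI parser reads, so generated ground truth round-trips exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .roi import (
    DIRECTIONS,
    ChainCodeRegion,
    Overlay,
    ROIPatch,
    extract_roi,
    parse_overlay,
    resize_bilinear,
    sample_normal_rois,
    write_overlay,
)

__all__ = [
    "BlobParams",
    "SyntheticConfig",
    "SyntheticImage",
    "Dataset",
    "DEFAULT_TEXTURE_PARAMS",
    "DDSM_CLASS_MIX",
    "generate_background",
    "insert_mass",
    "generate_dataset",
    "generate_patch_dataset",
    "write_pgm",
    "read_pgm",
]

_STEP_TO_CODE = {step: code for code, step in DIRECTIONS.items()}


@dataclass(frozen=True)
class BlobParams:
    """Clustered-lumpy texture parameters for one density grade."""

    blob_density: float  # blobs per 10^4 px^2
    blob_amplitude: float  # additive peak amplitude in [0, 1]
    blob_scale: float  # Gaussian sigma in pixels


#: Default texture parameters per BI-RADS density grade.  Blob rate and
#: amplitude increase with grade so mean intensity and clutter rise from
#: mainly-fatty (1) to extremely dense (4); scales approach typical mass
#: radii at high grades, which is what makes dense backgrounds confusable
#: with lesions.
DEFAULT_TEXTURE_PARAMS: dict[int, BlobParams] = {
    1: BlobParams(4.0, 0.05, 6.0),
    2: BlobParams(9.0, 0.20, 9.0),
    3: BlobParams(13.0, 0.29, 11.0),
    4: BlobParams(16.0, 0.38, 12.0),
}

#: Per-density class mix characteristic of DDSM-style mass/normal prototype
#: pools: (mass image fraction, malignant fraction among masses).  Grade 4
#: is heavily imbalanced toward normal tissue.
DDSM_CLASS_MIX: dict[int, tuple[float, float]] = {
    1: (291.1 / 571.1, 158.2 / 291.1),
    2: (752.3 / 1472.3, 402.9 / 752.3),
    3: (475.2 / 1034.8, 236.3 / 475.2),
    4: (187.2 / 620.1, 78.9 / 187.2),
}


@dataclass
class SyntheticConfig:
    """Configuration of the synthetic data generator.

    ``mass_fraction`` and ``malignant_fraction`` may be scalars or
    per-density mappings; the ``"ddsm-mix"`` preset of
    :func:`generate_dataset` installs the per-density DDSM-style mix.
    """

    seed: int = 0
    image_side: int = 192
    n_images_per_density: int = 20
    mass_fraction: float | Mapping[int, float] = 0.5
    malignant_fraction: float | Mapping[int, float] = 0.5
    mass_radius_range: tuple[float, float] = (14.0, 26.0)
    mass_contrast: float = 0.32
    density_texture_params: Mapping[int, BlobParams] = field(
        default_factory=lambda: dict(DEFAULT_TEXTURE_PARAMS)
    )
    noise_sigma: float = 0.02
    base_intensity: float = 0.08

    def __post_init__(self) -> None:
        if set(self.density_texture_params) != {1, 2, 3, 4}:
            raise ValueError("texture params must cover density levels 1-4 exactly")
        for d, p in self.density_texture_params.items():
            if not (0.0 <= p.blob_amplitude <= 1.0):
                raise ValueError(f"blob amplitude for density {d} outside [0, 1]")
            if p.blob_density < 0 or p.blob_scale <= 0:
                raise ValueError(f"invalid blob params for density {d}")
        for lo_d, hi_d in ((1, 2), (2, 3), (3, 4)):
            lo, hi = self.density_texture_params[lo_d], self.density_texture_params[hi_d]
            if hi.blob_amplitude < lo.blob_amplitude or hi.blob_density < lo.blob_density:
                raise ValueError(
                    "blob amplitude and density must be non-decreasing in density grade"
                )
        if not (0.0 <= self.noise_sigma <= 1.0):
            raise ValueError("noise_sigma must be in [0, 1]")
        if not (0.0 <= self.mass_contrast <= 1.0):
            raise ValueError("mass_contrast must be in [0, 1]")
        if self.mass_radius_range[0] < 2:
            raise ValueError("mass radii must be at least 2 px")
        if self.image_side < 64:
            raise ValueError("image side must be at least 64 px")

    def fraction(self, which: str, density: int) -> float:
        value = getattr(self, which)
        return float(value[density]) if isinstance(value, Mapping) else float(value)


@dataclass
class SyntheticImage:
    """Generated grayscale image plus its ground-truth mass annotations."""

    pixels: np.ndarray
    density: int
    regions: list[ChainCodeRegion] = field(default_factory=list)
    image_id: str = ""

    @property
    def truth_labels(self) -> list[str]:
        return [r.label for r in self.regions]

    def overlay(self) -> Overlay:
        return Overlay(image_shape=self.pixels.shape, regions=list(self.regions))


@dataclass
class Dataset:
    """In-memory dataset: images with annotations plus a manifest table."""

    images: list[SyntheticImage]
    manifest: pd.DataFrame
    config: SyntheticConfig


def generate_background(
    density: int,
    side: int,
    rng: np.random.Generator,
    config: SyntheticConfig | None = None,
) -> SyntheticImage:
    """Clustered-lumpy background for one density grade.

    Blob centres follow a homogeneous Poisson process over an extended
    domain (3 sigma margin beyond the image) so the texture is stationary up
    to the borders; by Campbell's theorem the blob contribution then has mean
    ``lambda * a * 2 pi s^2`` and variance ``lambda * a^2 * pi s^2`` per
    pixel, with ``lambda`` the blob rate per px^2.
    """
    if density not in (1, 2, 3, 4):
        raise ValueError(f"unknown density level {density}")
    if side < 64:
        raise ValueError("image side must be at least 64 px")
    cfg = config or SyntheticConfig()
    p = cfg.density_texture_params[density]
    margin = 3.0 * p.blob_scale
    ext = side + 2.0 * margin
    lam = p.blob_density / 1e4  # blobs per px^2
    n_blobs = rng.poisson(lam * ext * ext)
    centers = rng.uniform(-margin, side + margin, size=(n_blobs, 2))
    img = np.full((side, side), cfg.base_intensity, dtype=float)
    _render_blobs(img, centers, p.blob_amplitude, p.blob_scale)
    if cfg.noise_sigma > 0:
        img += rng.normal(0.0, cfg.noise_sigma, size=img.shape)
    np.clip(img, 0.0, 1.0, out=img)
    return SyntheticImage(pixels=img, density=density)


def _render_blobs(
    img: np.ndarray, centers: np.ndarray, amplitude: float, scale: float
) -> None:
    """Add Gaussian blobs in-place, each over a local 4-sigma window."""
    side = img.shape[0]
    half = int(math.ceil(4.0 * scale))
    for cr, cc in centers:
        r0 = max(0, int(math.floor(cr)) - half)
        r1 = min(side, int(math.ceil(cr)) + half + 1)
        c0 = max(0, int(math.floor(cc)) - half)
        c1 = min(side, int(math.ceil(cc)) + half + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        rr = np.arange(r0, r1, dtype=float) - cr
        cc_ = np.arange(c0, c1, dtype=float) - cc
        g = np.exp(-(rr[:, None] ** 2 + cc_[None, :] ** 2) / (2.0 * scale * scale))
        img[r0:r1, c0:c1] += amplitude * g


def _radius_profile(
    radius: float, rng: np.random.Generator, irregularity: float = 0.22
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random Fourier margin perturbation: orders, amplitudes, phases."""
    n_harm = int(rng.integers(3, 9))  # 3-8 harmonics
    orders = np.arange(2, 2 + n_harm)
    amps = irregularity * rng.uniform(0.2, 1.0, size=n_harm) / orders
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_harm)
    return orders, amps, phases


def _margin_radius(
    theta: np.ndarray, radius: float, orders, amps, phases
) -> np.ndarray:
    pert = np.zeros_like(theta)
    for k, a, ph in zip(orders, amps, phases):
        pert += a * np.cos(k * theta + ph)
    return radius * (1.0 + pert)


def _trace_boundary_chain(
    center: tuple[float, float], radius: float, orders, amps, phases
) -> tuple[tuple[int, int], tuple[int, ...]]:
    """Rasterize the analytic margin into a closed 8-connected chain code."""
    r0, c0 = center
    n_theta = max(256, int(16 * radius))
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    rad = _margin_radius(theta, radius, orders, amps, phases)
    rows = np.rint(r0 + rad * np.sin(theta)).astype(int)
    cols = np.rint(c0 + rad * np.cos(theta)).astype(int)
    # walk the sampled points, inserting king-move steps between them
    pts: list[tuple[int, int]] = [(int(rows[0]), int(cols[0]))]
    for r, c in list(zip(rows[1:], cols[1:])) + [(rows[0], cols[0])]:
        cur = pts[-1]
        while cur != (r, c):
            cur = (cur[0] + int(np.sign(r - cur[0])), cur[1] + int(np.sign(c - cur[1])))
            pts.append(cur)
    pts.pop()  # closing point repeats the start
    codes = []
    n = len(pts)
    for i in range(n):
        dr = pts[(i + 1) % n][0] - pts[i][0]
        dc = pts[(i + 1) % n][1] - pts[i][1]
        codes.append(_STEP_TO_CODE[(dr, dc)])
    return pts[0], tuple(codes)


def insert_mass(
    image: SyntheticImage,
    center: tuple[int, int],
    radius: float,
    contrast: float,
    rng: np.random.Generator,
    label: str = "malignant",
) -> SyntheticImage:
    """Add a bright lesion with an irregular margin; record its boundary.

    The lesion is additive: ``contrast * (1 - (r/R(theta))^2)^1.5`` inside
    the margin ``R(theta)``, a circle of the given radius perturbed by 3-8
    random low-order harmonics.  The traced margin is appended as a closed
    :class:`ChainCodeRegion`.  Raises ``ValueError`` if the lesion would
    cross the image border — placement is the caller's responsibility.
    """
    side = image.pixels.shape[0]
    r0, c0 = center
    orders, amps, phases = _radius_profile(radius, rng)
    max_r = radius * (1.0 + float(np.sum(amps)))
    if not (max_r + 1 <= r0 <= side - max_r - 2 and max_r + 1 <= c0 <= side - max_r - 2):
        raise ValueError(
            f"lesion of max radius {max_r:.1f} at {center} would cross the border"
        )
    start, codes = _trace_boundary_chain((float(r0), float(c0)), radius, orders, amps, phases)
    region = ChainCodeRegion(start=start, codes=codes, label=label)

    out = np.array(image.pixels, dtype=float)
    half = int(math.ceil(max_r)) + 1
    rr = np.arange(r0 - half, r0 + half + 1, dtype=float) - r0
    cc = np.arange(c0 - half, c0 + half + 1, dtype=float) - c0
    dist = np.hypot(rr[:, None], cc[None, :])
    theta = np.arctan2(rr[:, None], cc[None, :])
    r_margin = _margin_radius(theta, radius, orders, amps, phases)
    with np.errstate(invalid="ignore"):
        profile = np.where(
            dist <= r_margin,
            contrast * np.clip(1.0 - (dist / np.maximum(r_margin, 1e-9)) ** 2, 0.0, 1.0) ** 1.5,
            0.0,
        )
    out[r0 - half : r0 + half + 1, c0 - half : c0 + half + 1] += profile
    np.clip(out, 0.0, 1.0, out=out)
    return SyntheticImage(
        pixels=out,
        density=image.density,
        regions=image.regions + [region],
        image_id=image.image_id,
    )


def write_pgm(path: str | Path, pixels: np.ndarray) -> None:
    """Write a [0,1] float image as 16-bit binary PGM (P5, maxval 65535)."""
    arr = np.clip(np.asarray(pixels, dtype=float), 0.0, 1.0)
    q = np.rint(arr * 65535.0).astype(">u2")  # PGM 16-bit is big-endian
    h, w = q.shape
    with open(path, "wb") as fh:
        fh.write(f"P5\n{w} {h}\n65535\n".encode("ascii"))
        fh.write(q.tobytes())


def read_pgm(path: str | Path) -> np.ndarray:
    """Read a PGM written by :func:`write_pgm` back to [0,1] floats."""
    with Image.open(path) as im:
        arr = np.asarray(im, dtype=float)
    return arr / 65535.0


def generate_dataset(
    config: SyntheticConfig,
    out_dir: str | Path | None = None,
    preset: str | None = None,
) -> Dataset:
    """Generate a full density-graded image dataset with annotations.

    With ``preset="ddsm-mix"`` the per-density mass:normal image proportions
    and the malignant share among masses follow the DDSM-style class mix
    (:data:`DDSM_CLASS_MIX`), under which grade 4 is strongly imbalanced
    toward normal tissue.  With ``out_dir`` set, images are written as 16-bit
    PGM, annotations as overlay text files, and the manifest as CSV.
    """
    if preset is not None:
        if preset != "ddsm-mix":
            raise ValueError(f"unknown preset {preset!r}")
        config = replace(
            config,
            mass_fraction={d: m[0] for d, m in DDSM_CLASS_MIX.items()},
            malignant_fraction={d: m[1] for d, m in DDSM_CLASS_MIX.items()},
        )
    rng = np.random.default_rng(config.seed)
    images: list[SyntheticImage] = []
    rows = []
    for density in (1, 2, 3, 4):
        n = config.n_images_per_density
        n_mass = int(round(n * config.fraction("mass_fraction", density)))
        n_malig = int(round(n_mass * config.fraction("malignant_fraction", density)))
        for idx in range(n):
            img = generate_background(density, config.image_side, rng, config)
            img.image_id = f"d{density}_img{idx:04d}"
            if idx < n_mass:
                label = "malignant" if idx < n_malig else "benign"
                radius = float(rng.uniform(*config.mass_radius_range))
                margin = radius * 1.4 + 4.0
                r0 = int(rng.uniform(margin, config.image_side - margin))
                c0 = int(rng.uniform(margin, config.image_side - margin))
                img = insert_mass(img, (r0, c0), radius, config.mass_contrast, rng, label)
                img.image_id = f"d{density}_img{idx:04d}"
            images.append(img)
            rows.append(
                {
                    "image_id": img.image_id,
                    "density": density,
                    "n_regions": len(img.regions),
                    "label": img.regions[0].label if img.regions else "normal",
                }
            )
    manifest = pd.DataFrame(rows, columns=["image_id", "density", "n_regions", "label"])
    ds = Dataset(images=images, manifest=manifest, config=config)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for img in ds.images:
            write_pgm(out / f"{img.image_id}.pgm", img.pixels)
            (out / f"{img.image_id}.overlay.txt").write_text(write_overlay(img.overlay()))
        manifest.to_csv(out / "manifest.csv", index=False)
    return ds


def generate_patch_dataset(
    config: SyntheticConfig,
    patch_side: int = 64,
    n_normal_per_image: int = 4,
    preset: str | None = None,
) -> list[ROIPatch]:
    """Dataset straight to labelled, resized ROI patches.

    Every mass annotation round-trips through the overlay text dialect and
    the chain-code parser before extraction, exercising the same path real
    overlay files take.  Normal patches are sampled from the mass-free
    images with sides uniform on the range of mass bounding-square sides
    observed in the dataset, then everything is resized to ``patch_side``.
    """
    ds = generate_dataset(config, preset=preset)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    mass_patches: list[ROIPatch] = []
    normal_images: list[SyntheticImage] = []
    for img in ds.images:
        if not img.regions:
            normal_images.append(img)
            continue
        parsed = parse_overlay(write_overlay(img.overlay()))
        for region in parsed.regions:
            patch = extract_roi(img.pixels, region, img.density, source_id=img.image_id)
            if patch is not None:
                mass_patches.append(patch)
    if mass_patches:
        sides = [p.side for p in mass_patches]
        size_range = (min(sides), max(sides))
    else:
        size_range = (patch_side, patch_side)
    normal_patches: list[ROIPatch] = []
    for img in normal_images:
        normal_patches.extend(
            sample_normal_rois(
                img.pixels,
                n_normal_per_image,
                size_range,
                rng,
                density=img.density,
                source_id=img.image_id,
            )
        )
    return [resize_bilinear(p, patch_side) for p in mass_patches + normal_patches]
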