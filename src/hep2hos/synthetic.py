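"""Seeded generator of HEp-2-like single-cell images.

Six antinuclear-antibody staining patterns are emulated on a dark
background: homogeneous (uniform nuclear fill), speckled (dense
fine-grained multiplicative speckle), nucleolar (a few large bright
blobs), centromere (many small discrete dots), nuclear membrane (a
bright rim with a dim interior) and golgi (a small cluster of blobs
against one pole of the nucleus).  Each cell carries one of two
fluorescence-intensity levels: ``positive`` (bright) or
``intermediate`` (dim).

The generator exists so that the full pipeline — segmentation, Radon /
bispectral feature extraction, the L-moment layer and the softmax
classifier — can be exercised end to end with known ground truth.  It
is a caricature of indirect-immunofluorescence imagery, not a
photorealistic simulation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
from scipy import ndimage as ndi

CLASS_NAMES: tuple[str, ...] = (
    "homogeneous",
    "speckled",
    "nucleolar",
    "centromere",
    "nuclear_membrane",
    "golgi",
)
INTENSITY_LEVELS: tuple[str, ...] = ("positive", "intermediate")

# Foreground mean bands per intensity level (background stays in [0, 0.1]).
_LEVEL_BANDS = {"positive": (0.62, 0.70), "intermediate": (0.28, 0.40)}
_BACKGROUND = 0.03

#: Bounds on the number of centromere dots drawn at the default 64 px size.
CENTROMERE_DOT_RANGE = (30, 60)


@dataclass
class CellImage:
    """A single-cell grayscale image with optional ground-truth labels."""

    pixels: np.ndarray
    label: Optional[str] = None
    intensity_level: Optional[str] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("CellImage.pixels must be a 2-D array")
        h, w = self.pixels.shape
        if h < 16 or w < 16:
            raise ValueError("CellImage must be at least 16x16 pixels")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("CellImage pixels must be finite")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("CellImage pixels must lie in [0, 1]")
        if self.label is not None and self.label not in CLASS_NAMES:
            raise ValueError(
                f"unknown label {self.label!r}; expected one of {CLASS_NAMES}"
            )
        if self.intensity_level is not None and self.intensity_level not in INTENSITY_LEVELS:
            raise ValueError(
                f"unknown intensity level {self.intensity_level!r}; "
                f"expected one of {INTENSITY_LEVELS}"
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class GroundTruthMask:
    """Binary nucleus mask paired with a generated :class:`CellImage`."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        frac = self.mask.mean()
        if not (0.05 <= frac <= 0.95):
            raise ValueError(
                f"mask foreground fraction {frac:.3f} outside [0.05, 0.95]"
            )


@dataclass
class ManifestRecord:
    path: str
    label: str
    intensity_level: str
    split: str


@dataclass
class DatasetManifest:
    records: list[ManifestRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        paths = [r.path for r in self.records]
        if len(paths) != len(set(paths)):
            raise ValueError("manifest paths must be unique")
        for r in self.records:
            if r.label not in CLASS_NAMES:
                raise ValueError(f"unknown label {r.label!r} in manifest")

    def subset(self, split: str) -> "DatasetManifest":
        return DatasetManifest([r for r in self.records if r.split == split])

    def to_csv(self, path: Path | str) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["path", "label", "intensity_level", "split"])
            for r in self.records:
                writer.writerow([r.path, r.label, r.intensity_level, r.split])

    @classmethod
    def from_csv(cls, path: Path | str) -> "DatasetManifest":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            records = [
                ManifestRecord(
                    row["path"], row["label"], row["intensity_level"], row["split"]
                )
                for row in reader
            ]
        return cls(records)


def _ellipse_mask(
    size: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random nucleus ellipse: eccentricity ratio in [0.7, 1], random tilt.

    Returns the boolean mask and the signed normalized radius field
    ``r`` (r < 1 inside, = 1 on the boundary) used to draw rim bands.
    """
    a = 0.38 * size
    b = a * rng.uniform(0.7, 1.0)
    phi = rng.uniform(0, np.pi)
    cy = size / 2 + rng.uniform(-0.03, 0.03) * size
    cx = size / 2 + rng.uniform(-0.03, 0.03) * size
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(phi) + dy * np.sin(phi)
    v = -dx * np.sin(phi) + dy * np.cos(phi)
    r = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    return r < 1.0, r


def _place_dots(
    mask: np.ndarray,
    r_field: np.ndarray,
    n_target: int,
    min_dist: float,
    rng: np.random.Generator,
    max_tries: int = 4000,
) -> list[tuple[int, int]]:
    """Rejection-sample dot centres inside the nucleus, min_dist apart."""
    ys, xs = np.nonzero(mask & (r_field < 0.9))
    centres: list[tuple[int, int]] = []
    for _ in range(max_tries):
        if len(centres) >= n_target:
            break
        i = rng.integers(len(ys))
        y, x = int(ys[i]), int(xs[i])
        if all((y - cy) ** 2 + (x - cx) ** 2 >= min_dist**2 for cy, cx in centres):
            centres.append((y, x))
    return centres


def _disk(shape: tuple[int, int], cy: float, cx: float, radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def _texture(
    label: str,
    mask: np.ndarray,
    r_field: np.ndarray,
    size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Relative texture pattern over the nucleus, later normalized to unit
    foreground mean so the intensity level sets the absolute brightness."""
    p = np.zeros(mask.shape)
    if label == "homogeneous":
        p[mask] = 1.0
    elif label == "speckled":
        # dense multiplicative speckle with ~3 px grain: fluorescent
        # aggregates have physical extent, they are not pixel noise
        field = rng.normal(size=mask.shape)
        field = ndi.gaussian_filter(field, 1.0)
        field /= field.std()
        p[mask] = np.clip(1.0 + 0.5 * field, 0.05, None)[mask]
    elif label == "nucleolar":
        p[mask] = 0.55
        n_blobs = rng.integers(2, 6)
        ys, xs = np.nonzero(mask & (r_field < 0.5))
        for _ in range(n_blobs):
            i = rng.integers(len(ys))
            blob = _disk(mask.shape, ys[i], xs[i], rng.uniform(0.10, 0.15) * size)
            p[blob & mask] = 1.6
    elif label == "centromere":
        p[mask] = 0.8
        scale = (mask.sum() / (np.pi * (0.38 * 64) * (0.38 * 64) * 0.85)) ** 0.5
        lo, hi = CENTROMERE_DOT_RANGE
        n_dots = int(round(rng.integers(lo, hi + 1) * min(1.0, scale)))
        if mask.sum() / 4.2**2 > 1.3 * lo:  # room for the configured minimum
            n_dots = min(max(n_dots, lo), hi)
        centres = _place_dots(mask, r_field, n_dots, min_dist=4.2, rng=rng)
        for cy, cx in centres:
            dot = _disk(mask.shape, cy, cx, 1.7)
            p[dot & mask] = 1.6
    elif label == "nuclear_membrane":
        p[mask] = 0.6
        rim = mask & (r_field > 0.78)
        p[rim] = 1.7
    elif label == "golgi":
        p[mask] = 0.55
        pole = rng.uniform(-np.pi, np.pi)
        # blobs hug one pole of the nucleus boundary (in ellipse coordinates)
        n_blobs = rng.integers(1, 4)
        ys, xs = np.nonzero(mask)
        cy0, cx0 = ys.mean(), xs.mean()
        yy, xx = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
        theta = np.arctan2(yy - cy0, xx - cx0)
        for _ in range(n_blobs):
            ang = pole + rng.uniform(-0.45, 0.45)
            dth = np.angle(np.exp(1j * (theta - ang)))
            site = mask & (r_field > 0.65) & (r_field < 0.9) & (np.abs(dth) < 0.35)
            sy, sx = np.nonzero(site)
            if sy.size == 0:
                sy, sx = np.nonzero(mask & (r_field > 0.5))
            i = rng.integers(sy.size)
            blob = _disk(mask.shape, sy[i], sx[i], rng.uniform(0.09, 0.13) * size)
            p[blob & mask] = 1.6
    else:  # pragma: no cover - guarded by caller
        raise ValueError(f"unknown label {label!r}")
    return p


def generate_cell_image(
    label: str,
    intensity_level: str,
    size: int = 64,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> tuple[CellImage, GroundTruthMask]:
    """Render one synthetic cell and its ground-truth nucleus mask.

    Parameters
    ----------
    label
        One of the six staining-pattern classes.
    intensity_level
        ``"positive"`` (bright foreground, mean in [0.6, 0.9]) or
        ``"intermediate"`` (dim, mean in [0.25, 0.45]).
    size
        Image side length in pixels, at least 32.
    noise_sd
        Standard deviation of additive Gaussian noise (clipped to [0, 1]).
    seed
        Seeds all randomness; identical arguments give bit-identical output.
    """
    if label not in CLASS_NAMES:
        raise ValueError(f"unknown label {label!r}; expected one of {CLASS_NAMES}")
    if intensity_level not in INTENSITY_LEVELS:
        raise ValueError(
            f"unknown intensity level {intensity_level!r}; "
            f"expected one of {INTENSITY_LEVELS}"
        )
    if size < 32:
        raise ValueError("size must be at least 32 pixels")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")

    rng = np.random.default_rng(seed)
    mask, r_field = _ellipse_mask(size, rng)
    pattern = _texture(label, mask, r_field, size, rng)

    lo, hi = _LEVEL_BANDS[intensity_level]
    level = rng.uniform(lo, hi)
    fg = pattern[mask]
    # rescale so the clipped foreground mean hits the target level
    # (a single rescale undershoots for bright, high-contrast patterns)
    scale = level / fg.mean()
    for _ in range(12):
        clipped = np.clip(scale * fg, 0.0, 1.0)
        m = clipped.mean()
        if abs(m - level) < 1e-6:
            break
        scale *= level / m
    fg = np.clip(scale * fg, 0.0, 1.0)

    img = np.full((size, size), _BACKGROUND)
    img[mask] = fg
    img = np.clip(img, 0.0, 1.0)
    if noise_sd > 0:
        img = np.clip(img + rng.normal(0.0, noise_sd, img.shape), 0.0, 1.0)

    return (
        CellImage(img, label=label, intensity_level=intensity_level),
        GroundTruthMask(mask),
    )


def generate_dataset(
    n_per_class: int,
    intensity_mix: float = 0.5,
    size: int = 64,
    noise_sd: float = 0.02,
    seed: int = 0,
    out_dir: Optional[Path | str] = None,
    train_fraction: float = 0.8,
) -> tuple[DatasetManifest, list[tuple[CellImage, GroundTruthMask]]]:
    """Generate a balanced six-class dataset with a stratified 80/20 split.

    ``intensity_mix`` is the proportion of positive (bright) cells per
    class.  When ``out_dir`` is given, 8-bit grayscale PNGs plus a
    ``manifest.csv`` are written there; otherwise paths in the manifest
    are symbolic identifiers and the images are only returned in memory.
    """
    if n_per_class < 2:
        raise ValueError("n_per_class must be at least 2")
    if not 0 <= intensity_mix <= 1:
        raise ValueError("intensity_mix must be in [0, 1]")

    root = np.random.default_rng(seed)
    records: list[ManifestRecord] = []
    items: list[tuple[CellImage, GroundTruthMask]] = []
    for label in CLASS_NAMES:
        n_pos = int(round(intensity_mix * n_per_class))
        levels = ["positive"] * n_pos + ["intermediate"] * (n_per_class - n_pos)
        # stratified split within the class, seeded
        order = root.permutation(n_per_class)
        n_train = int(round(train_fraction * n_per_class))
        splits = np.empty(n_per_class, dtype=object)
        splits[order[:n_train]] = "train"
        splits[order[n_train:]] = "test"
        for i in range(n_per_class):
            img_seed = int(root.integers(0, 2**31 - 1))
            image, mask = generate_cell_image(
                label, levels[i], size=size, noise_sd=noise_sd, seed=img_seed
            )
            name = f"{label}_{i:04d}.png"
            records.append(ManifestRecord(name, label, levels[i], str(splits[i])))
            items.append((image, mask))
    manifest = DatasetManifest(records)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rec, (image, mask) in zip(manifest.records, items):
            iio.imwrite(
                out / rec.path, np.round(image.pixels * 255).astype(np.uint8)
            )
            iio.imwrite(
                out / (Path(rec.path).stem + "_mask.png"),
                (mask.mask * 255).astype(np.uint8),
            )
        manifest.to_csv(out / "manifest.csv")
    return manifest, items


def load_image(path: Path | str, **labels) -> CellImage:
    """Read a grayscale PNG/TIFF of any bit depth and scale it to [0, 1]."""
    raw = np.asarray(iio.imread(path))
    arr = raw.astype(float)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    if np.issubdtype(raw.dtype, np.integer):
        arr = arr / np.iinfo(raw.dtype).max
    elif arr.max() > 1:
        arr = arr / arr.max()
    return CellImage(np.clip(arr, 0.0, 1.0), **labels)
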