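"""Synthetic endoscopy-like texture channels.

Generates labeled, imbalanced, optionally noise-corrupted patch datasets
with the statistical structure the downstream pipeline assumes: a smoothed
random-field background, elliptical lesions carrying a second texture
class, mask-coverage patch labels, 7:2:1 splits and controllable label
noise.  Everything is a pure function of ``(spec, seed)``.

Textures are white noise convolved with a Gaussian kernel of class-specific
correlation length, plus a class-specific sinusoidal contrast term.  The
sinusoid amplitude is the separability dial: at high amplitude the lesion
class is linearly separable from background in co-occurrence statistics; at
amplitude 0 (and otherwise identical parameters) the two classes are drawn
from the same distribution.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from twincross.seeding import rng_for

CHANNEL_NAMES = ("GU", "GRS", "GPs", "GB")

#: benign / malignant patch quotas matching the printed per-channel counts
CHANNEL_QUOTAS = {
    "GU": (1857, 1351),
    "GRS": (1012, 4731),
    "GPs": (5406, 4224),
    "GB": (167, 1182),
}

DEFAULT_SPLIT_RATIOS = (0.7, 0.2, 0.1)


class ParameterError(ValueError):
    """Invalid generator parameters (e.g. unfittable ellipse ranges)."""


class QuotaError(RuntimeError):
    """A patch quota could not be met within the iteration cap."""


@dataclass(frozen=True)
class TextureParams:
    """Controls for one texture class."""

    base_intensity: float = 120.0
    noise_sigma: float = 40.0
    correlation_length: float = 1.5
    contrast_amplitude: float = 0.0
    contrast_period: float = 4.0

    def __post_init__(self) -> None:
        if self.correlation_length < 0:
            raise ParameterError("correlation_length must be >= 0")
        if self.contrast_period <= 0:
            raise ParameterError("contrast_period must be > 0")


@dataclass(frozen=True)
class LesionGeometry:
    """Ellipse sampling ranges. Semi-axes in pixels; rotation uniform [0, pi)."""

    n_lesions: tuple[int, int] = (1, 3)
    semi_axis: tuple[float, float] = (10.0, 30.0)

    def __post_init__(self) -> None:
        lo, hi = self.n_lesions
        if lo < 0 or hi < lo:
            raise ParameterError("n_lesions range must satisfy 0 <= lo <= hi")
        a_lo, a_hi = self.semi_axis
        if a_lo <= 0 or a_hi < a_lo:
            raise ParameterError("semi_axis range must satisfy 0 < lo <= hi")


@dataclass(frozen=True)
class ChannelSpec:
    """Full recipe for one lesion channel."""

    name: str
    n_benign: int
    n_malignant: int
    image_size: int = 200
    patch_size: int = 50
    lesion_geometry: LesionGeometry = field(default_factory=LesionGeometry)
    background: TextureParams = field(default_factory=TextureParams)
    lesion_texture: TextureParams = field(
        default_factory=lambda: TextureParams(contrast_amplitude=60.0)
    )
    label_noise_rate: float = 0.0
    coverage_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.name not in CHANNEL_NAMES:
            raise ParameterError(f"unknown channel name {self.name!r}")
        if self.n_benign < 0 or self.n_malignant < 0:
            raise ParameterError("patch quotas must be non-negative")
        if self.n_benign + self.n_malignant == 0:
            raise ParameterError("at least one patch must be requested")
        if self.patch_size < 2 or self.image_size < self.patch_size:
            raise ParameterError("need image_size >= patch_size >= 2")
        if not 0.0 <= self.label_noise_rate < 0.5:
            raise ParameterError("label_noise_rate must lie in [0, 0.5)")
        if not 0.0 < self.coverage_threshold <= 1.0:
            raise ParameterError("coverage_threshold must lie in (0, 1]")
        # Ellipses may overflow the frame (clipped at rasterization), but a
        # semi-axis beyond twice the frame is rejected as unfittable: every
        # placement would cover the whole image.
        if self.lesion_geometry.semi_axis[1] > 2 * self.image_size:
            raise ParameterError(
                "semi_axis upper bound exceeds 2 x image_size; "
                "ellipse range cannot fit inside the image"
            )


@dataclass(frozen=True)
class LabeledPatchDataset:
    """Patches, labels before/after noise, split tags and provenance."""

    channel: str
    patch_size: int
    patches: tuple[np.ndarray, ...]
    labels: np.ndarray  # clean labels, 0=benign 1=malignant
    noisy_labels: np.ndarray  # labels after injection (== labels if no noise)
    split: np.ndarray  # "train" | "test" | "val" per patch
    noise_index: frozenset[int]
    seed: int
    source_image: np.ndarray  # image index per patch
    grid_row: np.ndarray
    grid_col: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.patches)
        for arr in (self.labels, self.noisy_labels, self.split,
                    self.source_image, self.grid_row, self.grid_col):
            if len(arr) != n:
                raise ValueError("per-patch arrays must all have length n")
        if not self.noise_index <= set(range(n)):
            raise ValueError("noise_index must be a subset of patch ids")

    def __len__(self) -> int:
        return len(self.patches)

    @property
    def n_benign(self) -> int:
        return int(np.sum(self.labels == 0))

    @property
    def n_malignant(self) -> int:
        return int(np.sum(self.labels == 1))


def split_counts(
    n: int, ratios: tuple[float, float, float] = DEFAULT_SPLIT_RATIOS
) -> tuple[int, int, int]:
    """Partition ``n`` items into (train, test, val) counts.

    Rule: ``n_test = floor(r_test * n)``, ``n_val = floor(r_val * n)``,
    train takes the remainder.  With the default 7:2:1 ratios this
    reproduces the printed per-class split rows of the reference dataset.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    r_train, r_test, r_val = ratios
    if abs(r_train + r_test + r_val - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    if min(ratios) < 0:
        raise ValueError("ratios must be non-negative")
    n_test = int(np.floor(r_test * n))
    n_val = int(np.floor(r_val * n))
    n_train = n - n_test - n_val
    return n_train, n_test, n_val


def _texture_field(
    white: np.ndarray, params: TextureParams
) -> np.ndarray:
    """Smoothed random field plus sinusoidal contrast, float64.

    ``white`` is the shared white-noise draw: background and lesion fields
    are different smoothings of the *same* noise, so identical parameters
    give bit-identical fields and the mask boundary carries no seam signal
    of its own.
    """
    noise = white
    if params.correlation_length > 0:
        noise = gaussian_filter(noise, sigma=params.correlation_length)
        sd = noise.std()
        if sd > 0:
            noise = noise / sd
    out = params.base_intensity + params.noise_sigma * noise
    if params.contrast_amplitude != 0.0:
        rr, cc = np.mgrid[0 : white.shape[0], 0 : white.shape[1]].astype(float)
        w = 2.0 * np.pi / params.contrast_period
        out = out + params.contrast_amplitude * np.sin(w * rr) * np.sin(w * cc)
    return out


def _rasterize_ellipses(
    size: int,
    ellipses: list[tuple[float, float, float, float, float]],
) -> np.ndarray:
    """Binary mask of a union of ellipses; center-of-pixel inclusion test."""
    mask = np.zeros((size, size), dtype=np.uint8)
    if not ellipses:
        return mask
    rr, cc = np.mgrid[0:size, 0:size]
    py = rr + 0.5
    px = cc + 0.5
    for cy, cx, a, b, theta in ellipses:
        dy = py - cy
        dx = px - cx
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        mask |= ((u / a) ** 2 + (v / b) ** 2 <= 1.0).astype(np.uint8)
    return mask


def generate_texture_image(
    spec: ChannelSpec, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """One 8-bit grayscale image and its binary lesion mask.

    The mask is 1 exactly inside the union of sampled ellipses.  Texture
    inside the mask follows ``spec.lesion_texture``, outside
    ``spec.background``; both are smoothings of one shared noise draw (see
    :func:`_texture_field`).  Bit-identical for identical ``(spec, seed)``.
    """
    rng = rng_for(seed, "image")
    size = spec.image_size
    geo = spec.lesion_geometry

    n_lesions = int(rng.integers(geo.n_lesions[0], geo.n_lesions[1] + 1))
    ellipses = []
    for _ in range(n_lesions):
        a = float(rng.uniform(*geo.semi_axis))
        b = float(rng.uniform(*geo.semi_axis))
        cy = float(rng.uniform(0, size))
        cx = float(rng.uniform(0, size))
        theta = float(rng.uniform(0, np.pi))
        ellipses.append((cy, cx, a, b, theta))

    mask = _rasterize_ellipses(size, ellipses)
    white = rng.standard_normal((size, size))
    bg = _texture_field(white, spec.background)
    fg = _texture_field(white, spec.lesion_texture)
    image = np.where(mask.astype(bool), fg, bg)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    return image, mask


def inject_label_noise(
    dataset: LabeledPatchDataset, rate: float, seed: int
) -> LabeledPatchDataset:
    """Flip exactly ``round(rate * n)`` labels, recording flipped ids.

    Returns a new dataset; the input is untouched.  ``rate >= 0.5`` is
    rejected — noise would dominate signal.
    """
    if not 0.0 <= rate < 0.5:
        raise ValueError("noise rate must lie in [0, 0.5)")
    n = len(dataset)
    n_flip = int(np.floor(rate * n + 0.5))  # round-half-up, exact count
    if n_flip == 0:
        return replace(
            dataset,
            noisy_labels=dataset.labels.copy(),
            noise_index=frozenset(),
        )
    rng = rng_for(seed, "label-noise")
    flipped = rng.choice(n, size=n_flip, replace=False)
    noisy = dataset.labels.copy()
    noisy[flipped] = 1 - noisy[flipped]
    return replace(
        dataset, noisy_labels=noisy, noise_index=frozenset(int(i) for i in flipped)
    )


def build_channel_dataset(
    spec: ChannelSpec, seed: int, max_images: int = 2000
) -> LabeledPatchDataset:
    """Sample images until the benign/malignant patch quotas are met.

    Patches are labeled by mask coverage (malignant iff covered fraction
    >= ``spec.coverage_threshold``); split tags are assigned per class with
    the floor-based 7:2:1 rule; label noise is injected last when
    ``spec.label_noise_rate > 0``.
    """
    # local import: features depends on nothing here, but synthetic is the
    # bottom of the public dependency chain
    from twincross.features import decompose_into_patches, label_patch_from_mask

    p = spec.patch_size
    benign: list[tuple[np.ndarray, int, int, int]] = []
    malignant: list[tuple[np.ndarray, int, int, int]] = []
    for img_idx in range(max_images):
        if len(benign) >= spec.n_benign and len(malignant) >= spec.n_malignant:
            break
        image, mask = generate_texture_image(
            spec, rng_for(seed, "channel", spec.name, img_idx).integers(2**63)
        )
        grid = decompose_into_patches(image, p)
        for row, col, patch in grid.patches:
            label = label_patch_from_mask(
                (row, col), mask, p, spec.coverage_threshold
            )
            pool = malignant if label == 1 else benign
            quota = spec.n_malignant if label == 1 else spec.n_benign
            if len(pool) < quota:
                pool.append((patch, img_idx, row, col))
    if len(benign) < spec.n_benign or len(malignant) < spec.n_malignant:
        scarce = (
            "benign" if len(benign) < spec.n_benign else "malignant"
        )
        raise QuotaError(
            f"could not reach the {scarce} quota for channel {spec.name} "
            f"within {max_images} images "
            f"(benign {len(benign)}/{spec.n_benign}, "
            f"malignant {len(malignant)}/{spec.n_malignant})"
        )

    patches: list[np.ndarray] = []
    labels: list[int] = []
    split: list[str] = []
    src: list[int] = []
    rows: list[int] = []
    cols: list[int] = []
    rng = rng_for(seed, "splits", spec.name)
    for label, pool in ((0, benign), (1, malignant)):
        if not pool:
            continue
        n_train, n_test, n_val = split_counts(len(pool))
        tags = np.array(
            ["train"] * n_train + ["test"] * n_test + ["val"] * n_val
        )
        rng.shuffle(tags)
        for tag, (patch, img_idx, row, col) in zip(tags, pool):
            patches.append(patch)
            labels.append(label)
            split.append(str(tag))
            src.append(img_idx)
            rows.append(row)
            cols.append(col)

    labels_arr = np.asarray(labels, dtype=int)
    ds = LabeledPatchDataset(
        channel=spec.name,
        patch_size=p,
        patches=tuple(patches),
        labels=labels_arr,
        noisy_labels=labels_arr.copy(),
        split=np.asarray(split),
        noise_index=frozenset(),
        seed=seed,
        source_image=np.asarray(src, dtype=int),
        grid_row=np.asarray(rows, dtype=int),
        grid_col=np.asarray(cols, dtype=int),
    )
    if spec.label_noise_rate > 0:
        ds = inject_label_noise(ds, spec.label_noise_rate, seed)
    return ds


def write_dataset(
    dataset: LabeledPatchDataset, out_dir: str | Path
) -> Path:
    """Write patches as 8-bit grayscale PNGs plus a CSV manifest.

    Returns the manifest path.  Manifest columns: patch_id, channel, split,
    label, noisy_label, source_image, row, col.
    """
    out = Path(out_dir)
    patch_dir = out / "patches"
    patch_dir.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["patch_id", "channel", "split", "label", "noisy_label",
             "source_image", "row", "col"]
        )
        for i, patch in enumerate(dataset.patches):
            name = f"{dataset.channel}_{i:06d}.png"
            Image.fromarray(patch, mode="L").save(patch_dir / name)
            writer.writerow(
                [i, dataset.channel, dataset.split[i],
                 int(dataset.labels[i]), int(dataset.noisy_labels[i]),
                 int(dataset.source_image[i]),
                 int(dataset.grid_row[i]), int(dataset.grid_col[i])]
            )
    return manifest


def write_image_pair(
    image: np.ndarray, mask: np.ndarray, out_dir: str | Path, stem: str
) -> tuple[Path, Path]:
    """Write an image as grayscale PNG and its mask as a 0/255 PNG."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img_path = out / f"{stem}.png"
    mask_path = out / f"{stem}_mask.png"
    Image.fromarray(image, mode="L").save(img_path)
    Image.fromarray((mask * 255).astype(np.uint8), mode="L").save(mask_path)
    return img_path, mask_path


def default_channel_spec(
    name: str,
    scale: float = 1.0,
    contrast_amplitude: float = 60.0,
    label_noise_rate: float = 0.0,
    image_size: int = 200,
    patch_size: int = 50,
) -> ChannelSpec:
    """A channel spec with the printed benign/malignant imbalance.

    ``scale`` shrinks the quotas proportionally (minimum 1 per class) so
    tests and demos can run at desk scale while keeping the class ratio.
    """
    n_b, n_m = CHANNEL_QUOTAS[name]
    return ChannelSpec(
        name=name,
        n_benign=max(1, int(round(n_b * scale))),
        n_malignant=max(1, int(round(n_m * scale))),
        image_size=image_size,
        patch_size=patch_size,
        lesion_geometry=LesionGeometry(
            n_lesions=(1, 3),
            semi_axis=(0.2 * image_size, 0.45 * image_size),
        ),
        lesion_texture=TextureParams(contrast_amplitude=contrast_amplitude),
        label_noise_rate=label_noise_rate,
    )
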