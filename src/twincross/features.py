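"""Patch decomposition, GLCM texture features and the univariate screen.

The 22-dimensional feature vector is 11 co-occurrence statistics
(contrast, dissimilarity, homogeneity, energy, ASM, correlation, entropy,
GLCM mean, GLCM variance, cluster shade, cluster prominence), each averaged
over the four angles {0, 45, 90, 135} degrees, at pixel distances 1 and 2.
This composition is an interpretation: the source material names "22
features" without listing them, and all eleven statistics here are standard
co-occurrence measures.  The order is distance-major and fixed in
:data:`FEATURE_NAMES`.

Intensities are quantized to 32 gray levels by uniform binning of [0, 255]
(a 50x50 patch under-populates a 256-level matrix); RGB input is reduced to
luminance with ITU-R 601 weights before quantization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import fisher_exact
from skimage.feature import graycomatrix

DEFAULT_LEVELS = 32
DEFAULT_DISTANCES = (1, 2)
DEFAULT_ANGLES_DEG = (0.0, 45.0, 90.0, 135.0)

STAT_NAMES = (
    "contrast",
    "dissimilarity",
    "homogeneity",
    "energy",
    "asm",
    "correlation",
    "entropy",
    "glcm_mean",
    "glcm_variance",
    "cluster_shade",
    "cluster_prominence",
)

#: fixed 22-name order: distance-major, then the 11 statistics
FEATURE_NAMES = tuple(
    f"{stat}_d{d}" for d in DEFAULT_DISTANCES for stat in STAT_NAMES
)


class PatchGridError(ValueError):
    pass


@dataclass(frozen=True)
class PatchGrid:
    """Non-overlapping axis-aligned PxP tiling of an image.

    ``patches`` holds ``(row, col, array)`` triples with 0-based grid
    indices, origin at the image's top-left.  Border strips narrower than
    ``patch_size`` are dropped, never padded.
    """

    image_id: str
    patch_size: int
    patches: tuple[tuple[int, int, np.ndarray], ...]
    grid_shape: tuple[int, int]

    def __post_init__(self) -> None:
        n_rows, n_cols = self.grid_shape
        if len(self.patches) != n_rows * n_cols:
            raise PatchGridError("patch count must equal n_rows * n_cols")


@dataclass(frozen=True)
class GLCMFeatureVector:
    """22 named texture statistics for one patch."""

    patch_id: str
    values: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES
    levels: int = DEFAULT_LEVELS
    distances: tuple[int, ...] = DEFAULT_DISTANCES
    angles_deg: tuple[float, ...] = DEFAULT_ANGLES_DEG
    zero_variance: bool = False

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ValueError("values and names must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")


@dataclass(frozen=True)
class PatchAssociation:
    """Univariate odds-ratio screen result for one feature."""

    feature: str
    odds_ratio: float
    p_value: float
    significant: bool
    table: tuple[int, int, int, int]  # a, b, c, d


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Collapse RGB(A) to luminance (ITU-R 601); pass 2-D input through."""
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] in (3, 4):
        rgb = image[..., :3].astype(float)
        lum = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
        return np.clip(np.rint(lum), 0, 255).astype(np.uint8)
    raise ValueError(f"unsupported image shape {image.shape}")


def decompose_into_patches(
    image: np.ndarray, patch_size: int, image_id: str = ""
) -> PatchGrid:
    """Tile an image into non-overlapping PxP patches, dropping borders."""
    if patch_size < 2:
        raise PatchGridError("patch_size must be >= 2")
    gray = to_grayscale(np.asarray(image))
    h, w = gray.shape
    if h < patch_size or w < patch_size:
        raise PatchGridError(
            f"image {h}x{w} is smaller than patch_size {patch_size}"
        )
    n_rows = h // patch_size
    n_cols = w // patch_size
    patches = tuple(
        (
            r,
            c,
            gray[
                r * patch_size : (r + 1) * patch_size,
                c * patch_size : (c + 1) * patch_size,
            ],
        )
        for r in range(n_rows)
        for c in range(n_cols)
    )
    return PatchGrid(
        image_id=image_id,
        patch_size=patch_size,
        patches=patches,
        grid_shape=(n_rows, n_cols),
    )


def quantize(patch: np.ndarray, levels: int = DEFAULT_LEVELS) -> np.ndarray:
    """Uniformly bin [0, 255] intensities into ``levels`` gray levels."""
    arr = np.asarray(patch)
    if np.issubdtype(arr.dtype, np.floating):
        arr = np.clip(np.rint(arr), 0, 255)
    return ((arr.astype(np.int64) * levels) // 256).astype(np.uint8)


def compute_glcm(
    patch: np.ndarray,
    distances: tuple[int, ...] = DEFAULT_DISTANCES,
    angles_deg: tuple[float, ...] = DEFAULT_ANGLES_DEG,
    levels: int = DEFAULT_LEVELS,
) -> np.ndarray:
    """Normalized symmetric co-occurrence matrices.

    Returns an array of shape ``(levels, levels, n_distances, n_angles)``;
    each matrix is symmetric (pairs counted in both directions) and sums to
    1 within 1e-12.  A (distance, angle) combination with zero valid pixel
    pairs raises ``ValueError``.
    """
    q = quantize(patch, levels)
    angles = tuple(np.deg2rad(a) for a in angles_deg)
    raw = graycomatrix(
        q,
        distances=list(distances),
        angles=list(angles),
        levels=levels,
        symmetric=True,
        normed=False,
    ).astype(float)
    sums = raw.sum(axis=(0, 1))
    if np.any(sums == 0):
        bad = np.argwhere(sums == 0)[0]
        raise ValueError(
            f"no valid pixel pairs for distance={distances[bad[0]]}, "
            f"angle={angles_deg[bad[1]]} on a patch of shape {q.shape}"
        )
    return raw / sums


def _matrix_stats(m: np.ndarray) -> dict[str, float]:
    """The 11 statistics of one normalized symmetric GLCM."""
    levels = m.shape[0]
    i = np.arange(levels, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    diff = ii - jj
    p_i = m.sum(axis=1)  # marginal; equals column marginal by symmetry
    mu = float(np.sum(i * p_i))
    var = float(np.sum((i - mu) ** 2 * p_i))
    asm = float(np.sum(m**2))
    nz = m[m > 0]
    stats = {
        "contrast": float(np.sum(diff**2 * m)),
        "dissimilarity": float(np.sum(np.abs(diff) * m)),
        "homogeneity": float(np.sum(m / (1.0 + diff**2))),
        "energy": float(np.sqrt(asm)),
        "asm": asm,
        "entropy": float(-np.sum(nz * np.log(nz))),
        "glcm_mean": mu,
        "glcm_variance": var,
        "cluster_shade": float(np.sum((ii + jj - 2 * mu) ** 3 * m)),
        "cluster_prominence": float(np.sum((ii + jj - 2 * mu) ** 4 * m)),
    }
    if var <= 1e-15:
        # zero-variance patch: correlation undefined, 0 by convention
        stats["correlation"] = 0.0
    else:
        stats["correlation"] = float(
            np.sum((ii - mu) * (jj - mu) * m) / var
        )
    return stats


def glcm_feature_vector(
    glcms: np.ndarray,
    patch_id: str = "",
    distances: tuple[int, ...] = DEFAULT_DISTANCES,
    angles_deg: tuple[float, ...] = DEFAULT_ANGLES_DEG,
) -> GLCMFeatureVector:
    """Angle-averaged 22-value feature vector from :func:`compute_glcm` output."""
    if glcms.ndim != 4 or glcms.shape[2] != len(distances):
        raise ValueError("glcms must have shape (L, L, n_distances, n_angles)")
    if not np.allclose(glcms.sum(axis=(0, 1)), 1.0, atol=1e-9):
        raise ValueError("matrices must each be normalized to sum 1")
    values = []
    zero_var = False
    for d in range(len(distances)):
        per_angle = [
            _matrix_stats(glcms[:, :, d, a]) for a in range(glcms.shape[3])
        ]
        if any(s["glcm_variance"] <= 1e-15 for s in per_angle):
            zero_var = True
        for stat in STAT_NAMES:
            values.append(float(np.mean([s[stat] for s in per_angle])))
    names = tuple(f"{s}_d{d}" for d in distances for s in STAT_NAMES)
    return GLCMFeatureVector(
        patch_id=patch_id,
        values=np.asarray(values),
        names=names,
        levels=glcms.shape[0],
        distances=tuple(distances),
        angles_deg=tuple(angles_deg),
        zero_variance=zero_var,
    )


def patch_feature_vector(
    patch: np.ndarray, patch_id: str = "", **glcm_kwargs
) -> GLCMFeatureVector:
    """Convenience: quantize, build GLCMs and extract the 22 features."""
    distances = glcm_kwargs.get("distances", DEFAULT_DISTANCES)
    angles = glcm_kwargs.get("angles_deg", DEFAULT_ANGLES_DEG)
    glcms = compute_glcm(patch, **glcm_kwargs)
    return glcm_feature_vector(
        glcms, patch_id=patch_id, distances=distances, angles_deg=angles
    )


def feature_matrix(patches, **glcm_kwargs) -> np.ndarray:
    """Stack per-patch feature vectors into an (n, 22) matrix."""
    return np.vstack(
        [patch_feature_vector(p, **glcm_kwargs).values for p in patches]
    )


def label_patch_from_mask(
    coords: tuple[int, int],
    mask: np.ndarray,
    patch_size: int,
    tau: float = 0.5,
) -> int:
    """1 (malignant) iff lesion pixels cover >= tau of the patch area."""
    if not 0.0 < tau <= 1.0:
        raise ValueError("tau must lie in (0, 1]")
    r, c = coords
    window = mask[
        r * patch_size : (r + 1) * patch_size,
        c * patch_size : (c + 1) * patch_size,
    ]
    coverage = float(np.count_nonzero(window)) / float(patch_size**2)
    return int(coverage >= tau)


def fuse_feature_map(
    grid: PatchGrid, features: list[GLCMFeatureVector], feature_name: str
) -> np.ndarray:
    """Per-image map of one named feature, min-max normalized to [0, 1].

    Constant input maps to all-zeros.
    """
    if len(features) != len(grid.patches):
        raise ValueError("need exactly one feature vector per patch")
    n_rows, n_cols = grid.grid_shape
    out = np.zeros((n_rows, n_cols), dtype=float)
    for (r, c, _), fv in zip(grid.patches, features):
        if feature_name not in fv.names:
            raise KeyError(f"unknown feature name {feature_name!r}")
        out[r, c] = fv.values[fv.names.index(feature_name)]
    lo, hi = out.min(), out.max()
    if hi > lo:
        return (out - lo) / (hi - lo)
    return np.zeros_like(out)


def patch_association(
    values: np.ndarray,
    labels: np.ndarray,
    alpha_screen: float = 0.05,
    or_margin: float = 0.05,
    feature: str = "",
) -> PatchAssociation:
    """Univariate odds-ratio screen of one feature against patch labels.

    The feature is dichotomized at its median (high = strictly above);
    the 2x2 table gets a Haldane 0.5 correction when any cell is zero; the
    p-value is Fisher's two-sided exact test on the uncorrected table.
    Significance requires ``p < alpha_screen`` and an odds ratio outside
    the ``1 +/- or_margin`` band.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have equal length")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos < 2 or n_neg < 2:
        raise ValueError("need at least 2 patches per class")
    high = values > np.median(values)
    a = int(np.sum(high & (labels == 1)))
    b = int(np.sum(~high & (labels == 1)))
    c = int(np.sum(high & (labels == 0)))
    d = int(np.sum(~high & (labels == 0)))
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    _, p_value = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    effect = odds >= 1.0 + or_margin or odds <= 1.0 / (1.0 + or_margin)
    return PatchAssociation(
        feature=feature,
        odds_ratio=float(odds),
        p_value=float(p_value),
        significant=bool(p_value < alpha_screen and effect),
        table=(a, b, c, d),
    )


def write_feature_table(grid: PatchGrid, features, path) -> None:
    """CSV: patch_id, row, col, then the 22 feature columns."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patch_id", "row", "col", *FEATURE_NAMES])
        for (r, c, _), fv in zip(grid.patches, features):
            writer.writerow([fv.patch_id, r, c, *fv.values.tolist()])
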