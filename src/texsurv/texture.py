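"""First-order (histogram) and second-order (GLCM) tumour texture features.

Nine features per MR sequence are computed inside the tumour VOI:

first-order (intensity histogram / raw moments)
    entropy, uniformity, variance, skewness, kurtosis
second-order (grey-level co-occurrence matrix, GLCM)
    GLCM entropy, angular second moment (ASM), cluster prominence,
    cluster shade

Conventions (fixed here because commercial texture packages rarely state
them):

* Intensities are min-max quantized over the within-VOI range into
  ``bin_count`` equal-width grey levels (default 32); a constant VOI maps
  to a single level.
* Entropy and uniformity are computed on the quantized histogram; variance,
  skewness and kurtosis on the *raw* within-VOI intensities with
  population (n-denominator) moments.  Kurtosis is the non-excess
  (Pearson) standardized fourth moment by default.
* The GLCM pools co-occurrence counts over the 13 unique 3-D direction
  vectors at Chebyshev distance 1, counts both-ends-in-mask pairs only,
  is symmetrized by adding the transpose, and is normalized to sum 1.
* Both entropies use log base 2 (bits), with 0*log(0) == 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .voi import TumourVOI, VoxelVolume, make_voi, tumour_volume_cm3

__all__ = [
    "TextureConfig",
    "IntensityHistogram",
    "QuantizedVOI",
    "GLCMatrix",
    "DegenerateGLCMError",
    "FIRST_ORDER_FEATURES",
    "GLCM_FEATURES",
    "FEATURE_NAMES",
    "default_offsets_3d",
    "quantize",
    "histogram_features",
    "build_glcm",
    "glcm_features",
    "extract_features",
]

FIRST_ORDER_FEATURES = ("entropy", "uniformity", "variance", "skewness", "kurtosis")
GLCM_FEATURES = (
    "glcm_entropy",
    "angular_second_moment",
    "cluster_prominence",
    "cluster_shade",
)
FEATURE_NAMES = FIRST_ORDER_FEATURES + GLCM_FEATURES


class DegenerateGLCMError(ValueError):
    """No in-mask voxel pair exists for any requested offset."""


@dataclass(frozen=True)
class TextureConfig:
    """Feature-extraction settings.

    bin_count:
        Number of grey levels for both the histogram and the GLCM (>= 2).
    offsets:
        GLCM displacement vectors; ``None`` means the 13 unique 3-D
        directions at distance 1.
    symmetric:
        Symmetrize the GLCM by adding its transpose.
    kurtosis:
        "pearson" (non-excess, Gaussian -> 3) or "excess" (Gaussian -> 0).
    """

    bin_count: int = 32
    offsets: tuple[tuple[int, int, int], ...] | None = None
    symmetric: bool = True
    kurtosis: str = "pearson"

    def __post_init__(self) -> None:
        if self.bin_count < 2:
            raise ValueError("bin_count must be >= 2")
        if self.kurtosis not in ("pearson", "excess"):
            raise ValueError("kurtosis must be 'pearson' or 'excess'")


def default_offsets_3d() -> tuple[tuple[int, int, int], ...]:
    """The 13 unique direction vectors at Chebyshev distance 1 in 3-D.

    One representative per +/- pair of the 26-neighbourhood; with a
    symmetrized GLCM these cover all 26 neighbours.
    """
    offsets = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                v = (dx, dy, dz)
                if v == (0, 0, 0):
                    continue
                if v > (0, 0, 0):  # lexicographic: keep one of each +/- pair
                    offsets.append(v)
    assert len(offsets) == 13
    return tuple(offsets)


@dataclass(frozen=True)
class IntensityHistogram:
    """Normalized grey-level histogram over the within-VOI intensity range."""

    bin_count: int
    probabilities: np.ndarray
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (self.bin_count,) or np.any(p < 0):
            raise ValueError("probabilities must be a non-negative length-bin_count vector")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("histogram probabilities must sum to 1")
        object.__setattr__(self, "probabilities", p)


@dataclass(frozen=True)
class QuantizedVOI:
    """Grey-level labelled VOI: levels in [0, bin_count) inside the mask, -1 outside."""

    levels: np.ndarray
    mask: np.ndarray
    bin_count: int
    histogram: IntensityHistogram = field(repr=False)


def quantize(voi: TumourVOI, bin_count: int = 32) -> QuantizedVOI:
    """Min-max quantize within-VOI intensities into equal-width grey levels.

    Level of voxel x: floor((x - min) / (max - min) * bin_count), clipped to
    bin_count - 1 so the maximum falls in the top level.  A constant VOI
    maps every voxel to level 0.
    """
    if bin_count < 2:
        raise ValueError("bin_count must be >= 2")
    x = voi.intensities
    lo, hi = float(x.min()), float(x.max())
    if hi > lo:
        lev = np.floor((x - lo) / (hi - lo) * bin_count).astype(np.int64)
        np.clip(lev, 0, bin_count - 1, out=lev)
        edges = np.linspace(lo, hi, bin_count + 1)
    else:
        lev = np.zeros(x.shape, dtype=np.int64)
        edges = np.linspace(lo, lo + 1.0, bin_count + 1)
    counts = np.bincount(lev, minlength=bin_count).astype(float)
    hist = IntensityHistogram(bin_count, counts / counts.sum(), edges)
    levels = np.full(voi.mask.shape, -1, dtype=np.int64)
    levels[voi.mask] = lev
    return QuantizedVOI(levels=levels, mask=voi.mask, bin_count=bin_count, histogram=hist)


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def histogram_features(
    hist: IntensityHistogram,
    raw_intensities: np.ndarray,
    *,
    kurtosis: str = "pearson",
) -> dict[str, float]:
    """The five first-order features.

    entropy = -sum p_i log2 p_i and uniformity = sum p_i^2 over the
    histogram; variance, skewness, kurtosis are population central moments
    of the raw intensities.  A zero-variance (constant) VOI reports
    skewness = kurtosis = 0 and sets ``degenerate=1``.
    """
    p = hist.probabilities
    x = np.asarray(raw_intensities, dtype=float)
    mu = x.mean()
    m2 = float(((x - mu) ** 2).mean())
    out = {
        "entropy": _entropy_bits(p),
        "uniformity": float((p**2).sum()),
        "variance": m2,
    }
    if m2 > 0:
        m3 = float(((x - mu) ** 3).mean())
        m4 = float(((x - mu) ** 4).mean())
        out["skewness"] = m3 / m2**1.5
        kurt = m4 / m2**2
        out["kurtosis"] = kurt - 3.0 if kurtosis == "excess" else kurt
        out["degenerate"] = 0.0
    else:
        out["skewness"] = 0.0
        out["kurtosis"] = 0.0
        out["degenerate"] = 1.0
    return out


@dataclass(frozen=True)
class GLCMatrix:
    """Normalized grey-level co-occurrence matrix with its marginal means."""

    level_count: int
    matrix: np.ndarray
    offsets: tuple[tuple[int, int, int], ...]
    symmetric: bool

    def __post_init__(self) -> None:
        P = np.asarray(self.matrix, dtype=float)
        n = self.level_count
        if P.shape != (n, n) or np.any(P < 0):
            raise ValueError("GLCM must be a non-negative level_count^2 matrix")
        if abs(P.sum() - 1.0) > 1e-9:
            raise ValueError("GLCM must be normalized to sum 1")
        object.__setattr__(self, "matrix", P)

    @property
    def mu_x(self) -> float:
        i = np.arange(self.level_count)
        return float(i @ self.matrix.sum(axis=1))

    @property
    def mu_y(self) -> float:
        j = np.arange(self.level_count)
        return float(self.matrix.sum(axis=0) @ j)


def build_glcm(
    qvoi: QuantizedVOI,
    offsets: Iterable[Sequence[int]] | None = None,
    symmetric: bool = True,
) -> GLCMatrix:
    """Accumulate co-occurrence counts over the given voxel offsets.

    A pair is counted only when both ends lie inside the mask.  Counts from
    all offsets are pooled into one matrix before (optional)
    symmetrization and normalization.
    """
    offs = tuple(tuple(int(c) for c in o) for o in (offsets or default_offsets_3d()))
    if not offs:
        raise ValueError("offsets must be non-empty")
    n = qvoi.bin_count
    lev, mask = qvoi.levels, qvoi.mask
    counts = np.zeros((n, n), dtype=np.int64)
    for dx, dy, dz in offs:
        src = _shift_slices(mask.shape, (dx, dy, dz), source=True)
        dst = _shift_slices(mask.shape, (dx, dy, dz), source=False)
        if src is None:
            continue
        valid = mask[src] & mask[dst]
        if not valid.any():
            continue
        i = lev[src][valid]
        j = lev[dst][valid]
        counts += np.bincount(i * n + j, minlength=n * n).reshape(n, n)
    total = counts.sum()
    if total == 0:
        raise DegenerateGLCMError("no in-mask voxel pair for any offset")
    if symmetric:
        counts = counts + counts.T
    return GLCMatrix(
        level_count=n,
        matrix=counts / counts.sum(),
        offsets=offs,
        symmetric=symmetric,
    )


def _shift_slices(shape, offset, *, source: bool):
    """Slice tuples so that arr[src] and arr[dst] are offset by ``offset``."""
    slices = []
    for size, d in zip(shape, offset):
        if abs(d) >= size:
            return None
        if d >= 0:
            s = slice(0, size - d) if source else slice(d, size)
        else:
            s = slice(-d, size) if source else slice(0, size + d)
        slices.append(s)
    return tuple(slices)


def glcm_features(glcm: GLCMatrix) -> dict[str, float]:
    """GLCM entropy (bits), ASM, cluster prominence and cluster shade.

    cluster shade      = sum_ij (i + j - mu_x - mu_y)^3 P(i, j)
    cluster prominence = sum_ij (i + j - mu_x - mu_y)^4 P(i, j)
    """
    P = glcm.matrix
    n = glcm.level_count
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    d = i + j - glcm.mu_x - glcm.mu_y
    return {
        "glcm_entropy": _entropy_bits(P.ravel()),
        "angular_second_moment": float((P**2).sum()),
        "cluster_prominence": float((d**4 * P).sum()),
        "cluster_shade": float((d**3 * P).sum()),
    }


def extract_features(
    volume: VoxelVolume,
    voi: TumourVOI,
    config: TextureConfig | None = None,
) -> dict[str, float]:
    """All nine texture features plus tumour volume for one sequence.

    Deterministic for a fixed config; composes quantize ->
    histogram_features and build_glcm -> glcm_features.
    """
    cfg = config or TextureConfig()
    q = quantize(voi, cfg.bin_count)
    feats = histogram_features(q.histogram, voi.intensities, kurtosis=cfg.kurtosis)
    feats.pop("degenerate", None)
    if voi.voxel_count == 1:
        # a single voxel has no neighbour pair; report the constant-VOI limits
        feats.update(
            glcm_entropy=0.0,
            angular_second_moment=1.0,
            cluster_prominence=0.0,
            cluster_shade=0.0,
        )
    else:
        glcm = build_glcm(q, cfg.offsets, cfg.symmetric)
        feats.update(glcm_features(glcm))
    feats["volume_cm3"] = tumour_volume_cm3(voi, volume.spacing)
    return feats


def feature_row(
    per_sequence: Mapping[str, dict[str, float]],
    volume_cm3: float,
) -> dict[str, float]:
    """Flatten per-sequence features into one tidy row.

    Keys are ``<sequence>_<feature>`` with sequence labels lower-cased and
    stripped of non-alphanumerics ("CE-T1WI" -> "cet1wi"), plus one shared
    ``volume_cm3`` column.
    """
    row: dict[str, float] = {}
    for seq, feats in per_sequence.items():
        tag = "".join(c for c in seq.lower() if c.isalnum())
        for name in FEATURE_NAMES:
            row[f"{tag}_{name}"] = feats[name]
    row["volume_cm3"] = volume_cm3
    return row
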