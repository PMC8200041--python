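"""Gray-level co-occurrence texture features.

The co-occurrence matrix P records how often gray levels i and j occur in
pixel pairs at a fixed offset; the five classical statistics derived from it
summarize texture:

* ASM (angular second moment)  sum p^2            — texture homogeneity
* Entropy                      -sum p ln p        — randomness (inverse of ASM)
* IDM (inverse diff. moment)   sum p/(1+(i-j)^2)  — intensity homogeneity
* Contrast                     sum (i-j)^2 p      — local variation (inverse of IDM)
* Correlation                  sum (i-mu_i)(j-mu_j) p / (s_i s_j)

Defaults: 64 gray levels, distance 1, the four directions {0, 45, 90, 135}
degrees pooled, symmetric counting.  Pooling directions removes the
orientation dependence that would otherwise confound the spectral alignment
readout; 64 levels keeps the matrix of a 128-px crop well occupied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from skimage.feature import graycomatrix

__all__ = ["GLCMatrix", "TextureFeatures", "quantize", "glcm", "haralick_features"]

#: distance-1 offsets pooled by default, as (dr, dc)
DEFAULT_OFFSETS: Tuple[Tuple[int, int], ...] = ((0, 1), (1, 1), (1, 0), (1, -1))

# skimage angle convention producing those offsets at distance 1
_DEFAULT_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


@dataclass(frozen=True)
class GLCMatrix:
    """Normalized co-occurrence probabilities pooled over the given offsets."""

    P: np.ndarray
    levels: int
    offsets: Tuple[Tuple[int, int], ...]
    symmetric: bool

    def __post_init__(self) -> None:
        if np.any(self.P < 0):
            raise ValueError("co-occurrence probabilities must be >= 0")
        if abs(self.P.sum() - 1.0) > 1e-9:
            raise ValueError("co-occurrence matrix must be normalized to sum 1")
        if self.symmetric and not np.allclose(self.P, self.P.T, atol=1e-12):
            raise ValueError("symmetric co-occurrence matrix must equal its transpose")


@dataclass(frozen=True)
class TextureFeatures:
    asm: float
    entropy: float
    idm: float
    contrast: float
    correlation: float  # NaN when undefined (zero marginal variance)

    def as_dict(self) -> dict:
        return {
            "asm": self.asm,
            "entropy": self.entropy,
            "idm": self.idm,
            "contrast": self.contrast,
            "correlation": self.correlation,
        }


def quantize(pixels: np.ndarray, levels: int = 64) -> np.ndarray:
    """Linearly map the crop's [min, max] intensity range onto {0..levels-1}.

    A constant crop maps to level 0.
    """
    if levels < 2:
        raise ValueError("need at least 2 gray levels")
    pixels = np.asarray(pixels, dtype=float)
    lo, hi = pixels.min(), pixels.max()
    if hi == lo:
        return np.zeros(pixels.shape, dtype=np.uint16)
    idx = np.floor((pixels - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(idx, 0, levels - 1).astype(np.uint16)


def glcm(
    indexed: np.ndarray,
    levels: int = 64,
    offsets: Sequence[Tuple[int, int]] = DEFAULT_OFFSETS,
    symmetric: bool = True,
) -> GLCMatrix:
    """Pooled, normalized gray-level co-occurrence matrix of an indexed image."""
    indexed = np.asarray(indexed)
    if indexed.max(initial=0) >= levels:
        raise ValueError("indexed image has values >= levels")
    offsets = tuple((int(dr), int(dc)) for dr, dc in offsets)
    for dr, dc in offsets:
        if abs(dr) >= indexed.shape[0] or abs(dc) >= indexed.shape[1]:
            raise ValueError(f"offset {(dr, dc)} larger than image {indexed.shape}")

    if offsets == DEFAULT_OFFSETS:
        counts = graycomatrix(
            indexed.astype(np.uint8) if levels <= 256 else indexed,
            distances=[1],
            angles=list(_DEFAULT_ANGLES),
            levels=levels,
            symmetric=symmetric,
            normed=False,
        )[:, :, 0, :].sum(axis=2).astype(float)
    else:
        counts = np.zeros((levels, levels))
        for dr, dc in offsets:
            a = indexed[max(0, -dr) : indexed.shape[0] - max(0, dr),
                        max(0, -dc) : indexed.shape[1] - max(0, dc)]
            b = indexed[max(0, dr) :, max(0, dc) :][: a.shape[0], : a.shape[1]]
            np.add.at(counts, (a.ravel(), b.ravel()), 1.0)
        if symmetric:
            counts = counts + counts.T

    total = counts.sum()
    if total == 0:
        raise ValueError("no pixel pairs at the requested offsets")
    return GLCMatrix(P=counts / total, levels=levels, offsets=offsets, symmetric=symmetric)


def haralick_features(matrix: GLCMatrix) -> TextureFeatures:
    """The five texture statistics of a normalized co-occurrence matrix.

    Entropy uses the natural logarithm with 0*log 0 := 0.  Correlation is NaN
    (undefined) when either marginal standard deviation vanishes, i.e. for a
    flat crop; such records are dropped from classification downstream.
    """
    P = matrix.P
    if abs(P.sum() - 1.0) > 1e-9:
        raise ValueError("co-occurrence matrix is not normalized")
    G = P.shape[0]
    i = np.arange(G)[:, None]
    j = np.arange(G)[None, :]

    asm = float(np.sum(P**2))
    nz = P[P > 0]
    entropy = float(-np.sum(nz * np.log(nz)))
    idm = float(np.sum(P / (1.0 + (i - j) ** 2)))
    contrast = float(np.sum((i - j) ** 2 * P))

    pi = P.sum(axis=1)
    pj = P.sum(axis=0)
    mu_i = float(np.sum(np.arange(G) * pi))
    mu_j = float(np.sum(np.arange(G) * pj))
    var_i = float(np.sum((np.arange(G) - mu_i) ** 2 * pi))
    var_j = float(np.sum((np.arange(G) - mu_j) ** 2 * pj))
    if var_i <= 0 or var_j <= 0:
        correlation = math.nan
    else:
        correlation = float(
            np.sum((i - mu_i) * (j - mu_j) * P) / math.sqrt(var_i * var_j)
        )
    return TextureFeatures(asm=asm, entropy=entropy, idm=idm, contrast=contrast,
                           correlation=correlation)
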