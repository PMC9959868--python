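"""Bispectral-invariant features of Radon projections.

Each cell image is reduced to a set of 1-D Radon projections R[theta].
For one projection, let F(k) be its DFT after mean subtraction and
zero-padding, with frequency normalized so that the Nyquist bin is
k = 1.  The bispectrum is

    S(k1, k2) = F(k1) F(k2) F*(k1 + k2)

and for each slope a in (0, 1] the integrated bispectrum along the line
k2 = a k1,

    I(a) = sum over 0 < k1 <= 1 / (1 + a) of S(k1, a k1),

gives one invariant phase feature P(a) = atan2(Im I(a), Re I(a)).
P(a) is invariant to amplitude scaling of the signal (S scales by a
positive real cube) and to circular translation (the DFT shift phases
of the three factors cancel along the line k1 + k2 = k1 + a k1).

Off-grid values of S at k2 = a k1 are obtained by linear interpolation
between the two neighbouring on-grid bispectrum values S(k1, floor) and
S(k1, floor+1); since each on-grid S is exactly shift-invariant, so is
the interpolated line integral, to machine precision.

With the default configuration (projection angles 0..178 degrees in
steps of 2, FFT length 1024, 256 slopes) a 50 x 50 cell image maps to
90 x 256 = 23,040 features.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable

import numpy as np
from skimage.transform import radon as _sk_radon
from sklearn.base import BaseEstimator, TransformerMixin

from .synthetic import CellImage

__all__ = [
    "Projection",
    "FeatureVector",
    "FeatureConfig",
    "BispectralFeatures",
    "radon_projections",
    "bispectral_invariants",
    "extract_features",
]


@dataclass
class Projection:
    """One Radon projection: line integrals of the image along angle theta."""

    theta: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("projection values must be a nonempty 1-D vector")


@dataclass
class FeatureVector:
    """Concatenated bispectral-invariant phases, ordered (angle, slope)."""

    values: np.ndarray
    n_angles: int
    n_slopes: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.n_angles * self.n_slopes:
            raise ValueError("feature length must equal n_angles * n_slopes")


@dataclass(frozen=True)
class FeatureConfig:
    """Extraction settings.  Defaults give 90 angles x 256 slopes = 23,040
    features per image with an FFT length of 1024 per projection."""

    angle_start: float = 0.0
    angle_stop: float = 180.0
    angle_step: float = 2.0
    fft_len: int = 1024
    n_slopes: int = 256

    @property
    def angles(self) -> np.ndarray:
        if not (0 <= self.angle_start < self.angle_stop <= 180):
            raise ValueError("need 0 <= angle_start < angle_stop <= 180")
        if self.angle_step <= 0:
            raise ValueError("angle_step must be positive")
        angles = np.arange(self.angle_start, self.angle_stop, self.angle_step)
        if angles.size == 0:
            raise ValueError("empty projection angle set")
        return angles

    @property
    def n_angles(self) -> int:
        return int(self.angles.size)

    @property
    def n_features(self) -> int:
        return self.n_angles * self.n_slopes


def radon_projections(
    image: CellImage | np.ndarray,
    angle_start: float = 0.0,
    angle_stop: float = 180.0,
    angle_step: float = 2.0,
) -> list[Projection]:
    """Radon projections of the image for angles in [start, stop) at the
    given step.

    The continuous Radon transform preserves total mass at every angle;
    the discrete implementation only does so to interpolation accuracy,
    so each projection is rescaled to sum exactly to the image total.
    """
    px = image.pixels if isinstance(image, CellImage) else np.asarray(image, float)
    angles = FeatureConfig(angle_start, angle_stop, angle_step).angles
    sinogram = _sk_radon(px, theta=angles, circle=False)
    total = px.sum()
    out = []
    for i, theta in enumerate(angles):
        col = sinogram[:, i]
        s = col.sum()
        if total != 0 and s != 0:
            col = col * (total / s)
        out.append(Projection(float(theta), col))
    return out


try:  # numba accelerates the line-integral accumulation ~10x
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False


@lru_cache(maxsize=8)
def _line_tables(fft_len: int, n_slopes: int):
    """Precomputed gather indices for the line integrals.

    For slope a_i = i / n_slopes the on-grid k1 bins are j1 = 1..floor(M /
    (1 + a_i)) with M = fft_len // 2 the Nyquist bin; k2 = a_i * j1 falls
    between bins j0 and j0 + 1 with linear weight w.
    """
    M = fft_len // 2
    j1_all, j0_all, w_all, starts = [], [], [], []
    pos = 0
    for i in range(1, n_slopes + 1):
        a = i / n_slopes
        jmax = int(np.floor(M / (1.0 + a) + 1e-12))
        j1 = np.arange(1, jmax + 1)
        k2 = a * j1
        j0 = np.floor(k2 + 1e-12).astype(np.int64)
        w = k2 - j0
        starts.append(pos)
        pos += j1.size
        j1_all.append(j1)
        j0_all.append(j0)
        w_all.append(w)
    return (
        np.concatenate(j1_all),
        np.concatenate(j0_all),
        np.concatenate(w_all),
        np.asarray(starts, dtype=np.int64),
    )


def _accumulate_numpy(F, j1, j0, w, starts):
    n_slopes = starts.size
    I = np.empty((F.shape[0], n_slopes), dtype=complex)
    chunk = max(1, int(2e6 // max(j1.size, 1)))
    for lo in range(0, F.shape[0], chunk):
        Fc = F[lo : lo + chunk]
        A = Fc[:, j1]
        s0 = A * Fc[:, j0] * np.conj(Fc[:, j1 + j0])
        s1 = A * Fc[:, j0 + 1] * np.conj(Fc[:, j1 + j0 + 1])
        contrib = (1.0 - w) * s0 + w * s1
        I[lo : lo + chunk] = np.add.reduceat(contrib, starts, axis=1)
    return I


if _HAVE_NUMBA:

    @_njit(cache=False)
    def _accumulate_kernel(F, j1, j0, w, slope_id, n_slopes):  # pragma: no cover
        out = np.zeros((F.shape[0], n_slopes), dtype=np.complex128)
        for p in range(F.shape[0]):
            row = F[p]
            for i in range(j1.size):
                a = row[j1[i]]
                s0 = a * row[j0[i]] * np.conj(row[j1[i] + j0[i]])
                s1 = a * row[j0[i] + 1] * np.conj(row[j1[i] + j0[i] + 1])
                out[p, slope_id[i]] += (1.0 - w[i]) * s0 + w[i] * s1
        return out


@lru_cache(maxsize=8)
def _slope_ids(fft_len: int, n_slopes: int) -> np.ndarray:
    j1, _, _, starts = _line_tables(fft_len, n_slopes)
    ids = np.zeros(j1.size, dtype=np.int64)
    ids[starts[1:]] = 1
    return np.cumsum(ids)


def _phases_from_signals(Y: np.ndarray, fft_len: int, n_slopes: int) -> np.ndarray:
    """Invariant phases for a batch of zero-mean signals (rows of Y)."""
    j1, j0, w, starts = _line_tables(fft_len, n_slopes)
    F = np.fft.fft(Y, n=fft_len, axis=1)
    if _HAVE_NUMBA:
        I = _accumulate_kernel(
            np.ascontiguousarray(F), j1, j0, w, _slope_ids(fft_len, n_slopes), n_slopes
        )
    else:
        I = _accumulate_numpy(F, j1, j0, w, starts)
    return np.arctan2(I.imag, I.real)


def bispectral_invariants(
    projection: Projection | np.ndarray,
    fft_len: int = 1024,
    n_slopes: int = 256,
    subtract_mean: bool = True,
) -> np.ndarray:
    """Integrated-bispectrum phases P(a_i), a_i = i / n_slopes, i = 1..n_slopes.

    The projection is mean-subtracted (unless ``subtract_mean`` is
    False) and zero-padded to ``fft_len`` before the FFT.  All-zero
    projections return all-zero phases.
    """
    x = projection.values if isinstance(projection, Projection) else np.asarray(
        projection, float
    )
    if x.ndim != 1 or x.size == 0:
        raise ValueError("projection must be a nonempty 1-D vector")
    if fft_len < x.size:
        raise ValueError("fft_len must be at least the projection length")
    if n_slopes < 1:
        raise ValueError("n_slopes must be at least 1")
    y = x - x.mean() if subtract_mean else x
    return _phases_from_signals(y[None, :], fft_len, n_slopes)[0]


class BispectralFeatures(BaseEstimator, TransformerMixin):
    """Radon + integrated-bispectrum feature extractor (stateless transform).

    Accepts a 3-D array ``(n_images, h, w)`` or a sequence of 2-D images /
    :class:`CellImage` and returns ``(n_images, n_angles * n_slopes)``
    invariant phases in (-pi, pi].
    """

    def __init__(
        self,
        angle_start: float = 0.0,
        angle_stop: float = 180.0,
        angle_step: float = 2.0,
        fft_len: int = 1024,
        n_slopes: int = 256,
    ):
        self.angle_start = angle_start
        self.angle_stop = angle_stop
        self.angle_step = angle_step
        self.fft_len = fft_len
        self.n_slopes = n_slopes

    @property
    def config(self) -> FeatureConfig:
        return FeatureConfig(
            self.angle_start,
            self.angle_stop,
            self.angle_step,
            self.fft_len,
            self.n_slopes,
        )

    def fit(self, X=None, y=None):
        self.n_features_out_ = self.config.n_features
        return self

    def transform_one(self, image: CellImage | np.ndarray) -> FeatureVector:
        cfg = self.config
        projections = radon_projections(
            image, cfg.angle_start, cfg.angle_stop, cfg.angle_step
        )
        lengths = {p.values.size for p in projections}
        if max(lengths) > cfg.fft_len:
            raise ValueError("fft_len must be at least the projection length")
        Y = np.zeros((len(projections), max(lengths)))
        for i, p in enumerate(projections):
            v = p.values - p.values.mean()
            Y[i, : v.size] = v
        phases = _phases_from_signals(Y, cfg.fft_len, cfg.n_slopes)
        return FeatureVector(phases.ravel(), cfg.n_angles, cfg.n_slopes)

    def transform(self, X, y=None) -> np.ndarray:
        images: Iterable = X
        if isinstance(X, np.ndarray) and X.ndim == 3:
            images = list(X)
        return np.vstack([self.transform_one(img).values for img in images])


def extract_features(
    image: CellImage | np.ndarray, config: FeatureConfig | None = None
) -> FeatureVector:
    """Full feature vector of one image (see :class:`BispectralFeatures`)."""
    cfg = config or FeatureConfig()
    return BispectralFeatures(
        cfg.angle_start, cfg.angle_stop, cfg.angle_step, cfg.fft_len, cfg.n_slopes
    ).transform_one(image)
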