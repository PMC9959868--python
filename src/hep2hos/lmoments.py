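"""Sample L-moments via probability-weighted moments: the fixed hidden layer.

For an ascending sample H_1 <= ... <= H_n the probability-weighted
moments are

    b0 = (1/n) sum_j H_j
    b1 = (1/n) sum_{j>=2} H_j (j-1) / (n-1)
    b2 = (1/n) sum_{j>=3} H_j (j-1)(j-2) / ((n-1)(n-2))
    b3 = (1/n) sum_{j>=4} H_j (j-1)(j-2)(j-3) / ((n-1)(n-2)(n-3))

from which the first four sample L-moments follow:

    L1 = b0,  L2 = 2 b1 - b0,  L3 = 6 b2 - 6 b1 + b0,
    L4 = 20 b3 - 30 b2 + 12 b1 - b0.

The layer summarizes each group of features by the quadruple
(L-mean, L-scale, L-skewness, L-kurtosis) = (L1, L2/L1, L3/L2, L4/L2).
Ratios with an exactly zero denominator (constant groups in particular)
are defined as 0 so the representation stays finite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .features import FeatureVector

__all__ = [
    "PWMQuad",
    "LMomentQuad",
    "LMomentLayer",
    "pwm_betas",
    "l_statistics",
    "lmoment_descriptor",
]


@dataclass
class PWMQuad:
    beta0: float
    beta1: float
    beta2: float
    beta3: float


@dataclass
class LMomentQuad:
    """One (LM, LS, LSK, LK) summary of a feature group."""

    l_mean: float
    l_scale_ratio: float
    l_skewness: float
    l_kurtosis: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.l_mean, self.l_scale_ratio, self.l_skewness, self.l_kurtosis]
        )


def _pwm_weights(n: int) -> np.ndarray:
    """Rows: weights on the ascending order statistics for b0..b3."""
    j = np.arange(1, n + 1, dtype=float)
    w = np.empty((4, n))
    w[0] = 1.0 / n
    w[1] = (j - 1) / (n * (n - 1))
    w[2] = (j - 1) * (j - 2) / (n * (n - 1) * (n - 2))
    w[3] = (j - 1) * (j - 2) * (j - 3) / (n * (n - 1) * (n - 2) * (n - 3))
    return w


def pwm_betas(sample) -> PWMQuad:
    """Probability-weighted moments b0..b3 of a sample (sorted internally)."""
    x = np.sort(np.asarray(sample, dtype=float))
    if x.ndim != 1 or x.size < 4:
        raise ValueError("sample must be 1-D with at least 4 values")
    b = _pwm_weights(x.size) @ x
    return PWMQuad(*b)


def _ratios(L1, L2, L3, L4, constant: bool):
    if constant:
        return 0.0, 0.0, 0.0
    ls = L2 / L1 if L1 != 0 else 0.0
    lsk = L3 / L2 if L2 != 0 else 0.0
    lk = L4 / L2 if L2 != 0 else 0.0
    return ls, lsk, lk


def l_statistics(sample) -> LMomentQuad:
    """(L-mean, L-scale, L-skewness, L-kurtosis) of one sample.

    L2..L4 are translation invariant, so they are evaluated on the
    mean-centred sample; this avoids catastrophic cancellation for
    samples with a tiny spread around a large location.
    """
    x = np.asarray(sample, dtype=float)
    b = pwm_betas(x - x.mean())  # beta0 of the centred sample is ~0
    L2 = 2 * b.beta1 - b.beta0
    L3 = 6 * b.beta2 - 6 * b.beta1 + b.beta0
    L4 = 20 * b.beta3 - 30 * b.beta2 + 12 * b.beta1 - b.beta0
    L1 = float(x.mean())
    ls, lsk, lk = _ratios(L1, L2, L3, L4, constant=np.ptp(x) == 0)
    return LMomentQuad(L1, ls, lsk, lk)


def _l_statistics_rows(X: np.ndarray, scale_stat: str = "ratio") -> np.ndarray:
    """Vectorized (LM, LS, LSK, LK) per row of a 2-D array.

    ``scale_stat="ratio"`` reports LS = L2/L1; ``"raw"`` reports L2
    itself, which stays well behaved when the group location L1 is near
    zero (phase features are roughly zero-mean, so the ratio is wildly
    ill-conditioned there).
    """
    n = X.shape[1]
    if n < 4:
        raise ValueError("group size must be at least 4")
    L1 = X.mean(axis=1)
    S = np.sort(X - L1[:, None], axis=1)  # centring stabilizes L2..L4
    B = S @ _pwm_weights(n).T  # rows x (b0..b3) of the centred sample
    L2 = 2 * B[:, 1] - B[:, 0]
    L3 = 6 * B[:, 2] - 6 * B[:, 1] + B[:, 0]
    L4 = 20 * B[:, 3] - 30 * B[:, 2] + 12 * B[:, 1] - B[:, 0]
    constant = np.ptp(X, axis=1) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        if scale_stat == "ratio":
            ls = np.where(L1 != 0, L2 / L1, 0.0)
        elif scale_stat == "raw":
            ls = L2.copy()
        else:
            raise ValueError(f"unknown scale_stat {scale_stat!r}")
        lsk = np.where(L2 != 0, L3 / L2, 0.0)
        lk = np.where(L2 != 0, L4 / L2, 0.0)
    ls[constant] = lsk[constant] = lk[constant] = 0.0
    return np.column_stack([L1, ls, lsk, lk])


Grouping = Literal["per_slope", "per_angle", "global", "fixed_blocks"]


def lmoment_descriptor(
    features: FeatureVector,
    grouping: Grouping = "per_slope",
    block_size: Optional[int] = None,
    scale_stat: str = "raw",
) -> np.ndarray:
    """L-moment summary of a feature vector.

    ``per_slope`` (the default) groups features by bispectral slope and
    summarizes across projection angles; because L-moments are invariant
    to any permutation of the group, the descriptor is unchanged when an
    image rotation cyclically shifts the angle axis, making it robust to
    cell orientation.  With the default 256 slopes this yields a
    1024-element hidden representation.  ``per_angle`` groups by angle
    (90 angles -> 360 elements), ``global`` uses a single group (4
    elements), and ``fixed_blocks`` uses consecutive blocks of
    ``block_size`` features.
    """
    v = features.values
    if grouping == "per_slope":
        if features.n_angles < 4:
            raise ValueError("per_slope grouping needs at least 4 angles")
        blocks = v.reshape(features.n_angles, features.n_slopes).T
    elif grouping == "per_angle":
        if features.n_slopes < 4:
            raise ValueError("per_angle grouping needs at least 4 slopes")
        blocks = v.reshape(features.n_angles, features.n_slopes)
    elif grouping == "global":
        blocks = v.reshape(1, -1)
    elif grouping == "fixed_blocks":
        if block_size is None or block_size < 4:
            raise ValueError("fixed_blocks grouping needs block_size >= 4")
        if v.size % block_size != 0:
            raise ValueError("feature length must be divisible by block_size")
        blocks = v.reshape(-1, block_size)
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    return _l_statistics_rows(np.ascontiguousarray(blocks), scale_stat).ravel()


class LMomentLayer(BaseEstimator, TransformerMixin):
    """Fixed (untrained) L-moment transform over grouped features.

    transform maps ``(n_samples, n_angles * n_slopes)`` feature rows
    (angle-major, as produced by the extractor) to ``(n_samples,
    4 * n_groups)`` descriptors.  The layer has no learned state;
    ``fit`` only records the expected group structure.
    """

    def __init__(
        self,
        grouping: Grouping = "per_slope",
        n_slopes: int = 256,
        block_size: Optional[int] = None,
        scale_stat: str = "raw",
    ):
        self.grouping = grouping
        self.n_slopes = n_slopes
        self.block_size = block_size
        self.scale_stat = scale_stat

    def _group_size(self, n_features: int) -> int:
        if self.grouping in ("per_slope", "per_angle"):
            if self.n_slopes < 4 and self.grouping == "per_angle":
                raise ValueError("per_angle grouping needs at least 4 slopes")
            if n_features % self.n_slopes != 0:
                raise ValueError("feature length must be divisible by n_slopes")
            if self.grouping == "per_slope":
                n_angles = n_features // self.n_slopes
                if n_angles < 4:
                    raise ValueError("per_slope grouping needs at least 4 angles")
                return n_angles
            return self.n_slopes
        if self.grouping == "global":
            return n_features
        if self.grouping == "fixed_blocks":
            if self.block_size is None or self.block_size < 4:
                raise ValueError("fixed_blocks grouping needs block_size >= 4")
            if n_features % self.block_size != 0:
                raise ValueError("feature length must be divisible by block_size")
            return self.block_size
        raise ValueError(f"unknown grouping {self.grouping!r}")

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        self.group_size_ = self._group_size(X.shape[1])
        self.n_groups_ = X.shape[1] // self.group_size_
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        size = self._group_size(X.shape[1])
        n_groups = X.shape[1] // size
        if self.grouping == "per_slope":
            n_angles = X.shape[1] // self.n_slopes
            blocks = (
                X.reshape(X.shape[0], n_angles, self.n_slopes)
                .transpose(0, 2, 1)
                .reshape(X.shape[0] * self.n_slopes, n_angles)
            )
        else:
            blocks = X.reshape(X.shape[0] * n_groups, size)
        return _l_statistics_rows(
            np.ascontiguousarray(blocks), self.scale_stat
        ).reshape(X.shape[0], 4 * n_groups)
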