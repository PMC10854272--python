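"""Matrix-level harmonization: mean shift and the GAN input normalizations.

Mean shift translates every matrix of one site by the difference of the two
sites' element-wise mean matrices, clamping at zero:

    S'[i,j] = max(0, S[i,j] - mean_source[i,j] + mean_target[i,j]).

It aligns site means exactly (wherever no entry is clamped) but leaves
per-site variances untouched.

The GAN transforms are the deterministic pre/post-processing an
image-translation network needs to see inputs in [-1, 1]: a log-scale map for
streamline counts and a linear map for mean streamline lengths, both anchored
at the global maximum entry over all matrices of both sites. Only these
transforms are implemented here; the adversarial network itself is a separate
(pluggable) concern.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from connharm.io import (
    MEAN_LENGTH,
    STREAMLINE_COUNT,
    WEIGHTINGS,
    ConnectivityMatrix,
)

from connharm.combat import CombatModel, combat_fit, combat_apply  # noqa: F401  (re-export)


@dataclass
class SiteMeanMatrix:
    """Element-wise mean of one site's connectivity matrices."""

    site: str
    weighting: str
    values: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


def site_mean(matrices: Sequence[ConnectivityMatrix], site: str) -> SiteMeanMatrix:
    """Element-wise arithmetic mean over a site's subjects."""
    if not matrices:
        raise ValueError("site_mean of an empty list")
    weighting = matrices[0].weighting
    n = matrices[0].n_nodes
    for m in matrices:
        if m.weighting != weighting:
            raise ValueError("mixed weightings in site_mean")
        if m.n_nodes != n:
            raise ValueError("dimension mismatch in site_mean")
    mean = np.mean([m.values for m in matrices], axis=0)
    return SiteMeanMatrix(site=site, weighting=weighting, values=mean)


def mean_shift(
    source: Sequence[ConnectivityMatrix],
    source_mean: SiteMeanMatrix,
    target_mean: SiteMeanMatrix,
) -> list[ConnectivityMatrix]:
    """Shift each source matrix by (target mean - source mean), clamped at 0."""
    if source_mean.weighting != target_mean.weighting:
        raise ValueError("source and target means have different weightings")
    if source_mean.values.shape != target_mean.values.shape:
        raise ValueError("source and target means have different shapes")
    delta = target_mean.values - source_mean.values
    out = []
    for m in source:
        if m.weighting != source_mean.weighting:
            raise ValueError(f"matrix {m.subject_id} weighting differs from the site means")
        if m.values.shape != delta.shape:
            raise ValueError(f"matrix {m.subject_id} dimension mismatch")
        shifted = np.maximum(0.0, m.values + delta)
        out.append(ConnectivityMatrix(m.subject_id, m.weighting, shifted))
    return out


@dataclass
class GanNormalizationParams:
    """Anchor of the [-1, 1] normalization: the largest entry over both sites."""

    global_max: float
    weighting: str

    def __post_init__(self) -> None:
        if self.weighting not in WEIGHTINGS:
            raise ValueError(f"unknown weighting {self.weighting!r}")
        if not self.global_max > 0:
            raise ValueError("global_max must be > 0")


def gan_params(matrices: Iterable[ConnectivityMatrix], weighting: str) -> GanNormalizationParams:
    """Compute the global maximum over all matrices (both sites) of one weighting."""
    mx = 0.0
    seen = False
    for m in matrices:
        if m.weighting != weighting:
            raise ValueError("gan_params got a matrix of the wrong weighting")
        mx = max(mx, float(m.values.max()))
        seen = True
    if not seen:
        raise ValueError("gan_params of an empty list")
    return GanNormalizationParams(global_max=mx, weighting=weighting)


def gan_normalize(m: ConnectivityMatrix, p: GanNormalizationParams) -> np.ndarray:
    """Map a matrix into [-1, 1] for a GAN.

    Streamline counts: M' = ln(M) / (0.5 ln(global_max)) - 1, with the zero
    count mapped to -1 (the floor), preserving sparsity; counts must be 0 or
    >= 1 (streamline counts are integers), since 0 < M < 1 would fall below -1.
    Mean lengths: M' = M / (0.5 global_max) - 1.
    """
    if m.weighting != p.weighting:
        raise ValueError("matrix and normalization params have different weightings")
    v = m.values
    if float(v.max()) > p.global_max * (1 + 1e-12):
        raise ValueError(f"entry {v.max()} exceeds global_max {p.global_max}")
    if m.weighting == STREAMLINE_COUNT:
        if p.global_max <= 1:
            raise ValueError("count global_max must exceed 1 for the log normalization")
        frac = (v > 0) & (v < 1)
        if frac.any():
            i, j = np.argwhere(frac)[0]
            raise ValueError(
                f"count entry {v[i, j]} at ({i}, {j}) in (0, 1); counts must be 0 or >= 1"
            )
        with np.errstate(divide="ignore"):
            out = np.where(v > 0, np.log(np.where(v > 0, v, 1.0)) / (0.5 * np.log(p.global_max)) - 1.0, -1.0)
    else:
        out = v / (0.5 * p.global_max) - 1.0
    return out


def gan_denormalize(
    values: np.ndarray, p: GanNormalizationParams, subject_id: str = "denormalized"
) -> ConnectivityMatrix:
    """Exact inverse of :func:`gan_normalize` on [-1, 1] inputs.

    For counts, -1 maps back to 0 (the sparsity floor).
    """
    v = np.asarray(values, dtype=float)
    if v.min() < -1 - 1e-12 or v.max() > 1 + 1e-12:
        raise ValueError("normalized entries must lie in [-1, 1]")
    if p.weighting == STREAMLINE_COUNT:
        out = np.where(v > -1, np.exp((v + 1.0) * 0.5 * np.log(p.global_max)), 0.0)
    else:
        out = (v + 1.0) * 0.5 * p.global_max
    return ConnectivityMatrix(subject_id, p.weighting, out)
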