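"""The 18 intensity features.

Twelve are plain statistics of the raw in-region voxel intensities; the six
``h_``-prefixed features are statistics of the quantized-level histogram
(``h_energy`` on raw bin counts, the rest on the normalized histogram over
levels 1..n_levels).  Conventions, pinned once: population (1/n) variance;
skewness is the population third standardized moment; kurtosis is non-excess
(kurtosis of a Gaussian is 3).  Degenerate moments of a constant region are
substituted by their documented limits (0) and flagged.
"""

from __future__ import annotations

import numpy as np

from cerebrad.features.catalogue import INTENSITY_FEATURES
from cerebrad.features.quantization import QuantizedRegion

__all__ = ["intensity_features"]


def _moments(x: np.ndarray, w: np.ndarray | None = None):
    """Mean, population variance, skewness, non-excess kurtosis (weighted)."""
    if w is None:
        w = np.full(x.shape, 1.0 / x.size)
    support = x[w > 0]
    if support.size and np.ptp(support) == 0:  # constant support: exact zeros
        return float(support[0]), 0.0, 0.0, 0.0, True
    mu = float(np.sum(w * x))
    var = float(np.sum(w * (x - mu) ** 2))
    if var <= 0:
        return mu, 0.0, 0.0, 0.0, True
    sd = np.sqrt(var)
    skew = float(np.sum(w * ((x - mu) / sd) ** 3))
    kurt = float(np.sum(w * ((x - mu) / sd) ** 4))
    return mu, var, skew, kurt, False


def intensity_features(q: QuantizedRegion) -> tuple[dict[str, float], dict[str, bool]]:
    """Compute the 18 intensity features of a quantized region.

    Returns ``(values, degenerate_flags)`` keyed by catalogue feature name.
    """
    x = np.asarray(q.voxel_values, dtype=float)
    flags = {name: False for name in INTENSITY_FEATURES}

    mu, var, skew, kurt, degen = _moments(x)
    if degen:
        flags["skewness"] = flags["kurtosis"] = True

    counts = q.histogram().astype(float)
    p = counts / counts.sum()
    levels = np.arange(1, q.n_levels + 1, dtype=float)
    h_mu, h_var, h_skew, h_kurt, h_degen = _moments(levels, w=p)
    if h_degen:
        flags["h_skewness"] = flags["h_kurtosis"] = True

    values = {
        "energy": float(np.sum(x**2)),
        "h_energy": float(np.sum(counts**2)),
        "kurtosis": kurt,
        "max": float(x.max()),
        "mean_absolute_deviation": float(np.mean(np.abs(x - mu))),
        "mean": mu,
        "median": float(np.median(x)),
        "min": float(x.min()),
        "range": float(x.max() - x.min()),
        "root_mean_square": float(np.sqrt(np.mean(x**2))),
        "skewness": skew,
        "standard_deviation": float(np.sqrt(var)),
        "h_uniformity": float(np.sum(p**2)),
        "variance": var,
        "h_mean": h_mu,
        "h_variance": h_var,
        "h_skewness": h_skew,
        "h_kurtosis": h_kurt,
    }
    return values, flags
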