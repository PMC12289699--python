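"""The 39 texture features from the GLCM, GLRLM, GLSZM and NGTDM matrices.

Definitions follow the widely used MATLAB texture-analysis conventions for
these four families.  Degenerate inputs (constant or single-voxel regions,
empty matrices) are substituted by each feature's documented limit and
flagged; no feature ever returns a non-finite value.
"""

from __future__ import annotations

import numpy as np

from cerebrad.features.catalogue import TEXTURE_FEATURES
from cerebrad.features.matrices import TextureMatrices

__all__ = ["texture_features", "EPS"]

#: Guard for NGTDM (and other) vanishing denominators.
EPS = 1e-6


def _glcm_features(m: TextureMatrices, flags: dict[str, bool]) -> dict[str, float]:
    p = m.glcm_normalized
    n = m.n_levels
    i = np.arange(1, n + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    if p.sum() <= 0:
        # no voxel pairs at all (single-voxel region)
        for name in ("glcm_energy", "glcm_contrast", "glcm_correlation",
                     "glcm_homogeneity", "glcm_variance", "glcm_sum_average",
                     "glcm_entropy", "glcm_dissimilarity"):
            flags[name] = True
        return {
            "glcm_energy": 1.0,
            "glcm_contrast": 0.0,
            "glcm_correlation": 0.0,
            "glcm_homogeneity": 1.0,
            "glcm_variance": 0.0,
            "glcm_sum_average": 0.0,
            "glcm_entropy": 0.0,
            "glcm_dissimilarity": 0.0,
        }

    pi = p.sum(axis=1)  # marginal (symmetric: rows == cols)
    mu = float(np.sum(i * pi))
    var = float(np.sum((i - mu) ** 2 * pi))

    if var > 0:
        correlation = float(np.sum((ii - mu) * (jj - mu) * p) / var)
    else:
        correlation = 0.0
        flags["glcm_correlation"] = True

    # sum average over the diagonal-sum distribution p_{x+y}(k), k = 2..2n
    k = np.arange(2, 2 * n + 1, dtype=float)
    p_sum = np.array([np.trace(np.fliplr(p), offset=n - 1 - d) for d in range(2 * n - 1)])

    nz = p[p > 0]
    return {
        "glcm_energy": float(np.sum(p**2)),
        "glcm_contrast": float(np.sum((ii - jj) ** 2 * p)),
        "glcm_correlation": correlation,
        "glcm_homogeneity": float(np.sum(p / (1.0 + np.abs(ii - jj)))),
        "glcm_variance": var,
        "glcm_sum_average": float(np.sum(k * p_sum)),
        "glcm_entropy": float(-np.sum(nz * np.log2(nz))),
        "glcm_dissimilarity": float(np.sum(np.abs(ii - jj) * p)),
    }


def _run_zone_features(
    counts: np.ndarray, n_voxels: int, prefix: str, names: tuple[str, ...],
    flags: dict[str, bool]
) -> dict[str, float]:
    """Shared GLRLM/GLSZM feature formulas (runs and zones are analogous)."""
    total = counts.sum()
    out = {name: 0.0 for name in names}
    if total <= 0:
        for name in names:
            flags[name] = True
        return out
    n_levels, max_len = counts.shape
    i = np.arange(1, n_levels + 1, dtype=float)[:, None]
    j = np.arange(1, max_len + 1, dtype=float)[None, :]
    p = counts / total
    mu_i = float(np.sum(i * p))
    mu_j = float(np.sum(j * p))
    short = "short_run" if prefix == "glrlm" else "small_zone"
    long_ = "long_run" if prefix == "glrlm" else "large_zone"
    run = "run_length" if prefix == "glrlm" else "zone_size"
    low = "low_gray_level_run" if prefix == "glrlm" else "low_gray_level_zone"
    high = "high_gray_level_run" if prefix == "glrlm" else "high_gray_level_zone"
    pct = "run_percentage" if prefix == "glrlm" else "zone_percentage"
    out = {
        f"{prefix}_{short}_emphasis": float(np.sum(p / j**2)),
        f"{prefix}_{long_}_emphasis": float(np.sum(p * j**2)),
        f"{prefix}_gray_level_nonuniformity": float(np.sum(counts.sum(axis=1) ** 2) / total),
        f"{prefix}_{run}_nonuniformity": float(np.sum(counts.sum(axis=0) ** 2) / total),
        f"{prefix}_{pct}": float(total / n_voxels),
        f"{prefix}_{low}_emphasis": float(np.sum(p / i**2)),
        f"{prefix}_{high}_emphasis": float(np.sum(p * i**2)),
        f"{prefix}_{short}_low_gray_level_emphasis": float(np.sum(p / (i**2 * j**2))),
        f"{prefix}_{short}_high_gray_level_emphasis": float(np.sum(p * i**2 / j**2)),
        f"{prefix}_{long_}_low_gray_level_emphasis": float(np.sum(p * j**2 / i**2)),
        f"{prefix}_{long_}_high_gray_level_emphasis": float(np.sum(p * i**2 * j**2)),
        f"{prefix}_gray_level_variance": float(np.sum(p * (i - mu_i) ** 2)),
        f"{prefix}_{run}_variance": float(np.sum(p * (j - mu_j) ** 2)),
    }
    assert set(out) == set(names)
    return out


def _ngtdm_features(m: TextureMatrices, flags: dict[str, bool]) -> dict[str, float]:
    p = m.ngtdm_p
    s = m.ngtdm_s
    n_total = m.ngtdm_n.sum()
    occupied = np.nonzero(p > 0)[0]
    names = ("ngtdm_coarseness", "ngtdm_contrast", "ngtdm_busyness",
             "ngtdm_complexity", "ngtdm_strength")
    if n_total <= 0 or occupied.size == 0:
        for name in names:
            flags[name] = True
        return {name: 0.0 for name in names}

    levels = occupied + 1.0
    pi = p[occupied]
    si = s[occupied]
    ng = occupied.size

    coarseness = 1.0 / (EPS + float(np.sum(pi * si)))

    if ng > 1:
        dl = levels[:, None] - levels[None, :]
        pp = pi[:, None] * pi[None, :]
        contrast = float(np.sum(pp * dl**2) / (ng * (ng - 1)) * (s.sum() / n_total))
        ipi = levels * pi
        busy_den = float(np.sum(np.abs(ipi[:, None] - ipi[None, :])))
        busyness = float(np.sum(pi * si)) / busy_den if busy_den > EPS else 0.0
        if busy_den <= EPS:
            flags["ngtdm_busyness"] = True
        psum = pi[:, None] + pi[None, :]
        complexity = float(
            np.sum(np.abs(dl) / (n_total * psum) * (pi[:, None] * si[:, None] + pi[None, :] * si[None, :]))
        )
        strength = float(np.sum(psum * dl**2)) / (EPS + float(s.sum()))
    else:
        contrast = busyness = complexity = strength = 0.0
        for name in ("ngtdm_contrast", "ngtdm_busyness", "ngtdm_complexity", "ngtdm_strength"):
            flags[name] = True

    return {
        "ngtdm_coarseness": coarseness,
        "ngtdm_contrast": contrast,
        "ngtdm_busyness": busyness,
        "ngtdm_complexity": complexity,
        "ngtdm_strength": strength,
    }


def texture_features(m: TextureMatrices) -> tuple[dict[str, float], dict[str, bool]]:
    """Compute the 39 texture features; returns ``(values, degenerate_flags)``."""
    flags = {name: False for name in TEXTURE_FEATURES}
    from cerebrad.features.catalogue import GLRLM_FEATURES, GLSZM_FEATURES

    values: dict[str, float] = {}
    values.update(_glcm_features(m, flags))
    values.update(_run_zone_features(m.glrlm, m.n_voxels, "glrlm", GLRLM_FEATURES, flags))
    values.update(_run_zone_features(m.glszm, m.n_voxels, "glszm", GLSZM_FEATURES, flags))
    values.update(_ngtdm_features(m, flags))
    if m.degenerate:
        for name in flags:
            flags[name] = True
    ordered = {name: values[name] for name in TEXTURE_FEATURES}
    assert all(np.isfinite(v) for v in ordered.values())
    return ordered, flags
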