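"""Region-level feature extraction: the full 57-feature vector."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cerebrad.features.catalogue import FEATURE_NAMES, N_FEATURES
from cerebrad.features.intensity import intensity_features
from cerebrad.features.matrices import build_matrices
from cerebrad.features.quantization import quantize_region

__all__ = ["RegionFeatureVector", "extract_region_features", "DEFAULT_MIN_VOXELS"]

#: Regions smaller than this are extracted but fully flagged for imputation.
DEFAULT_MIN_VOXELS = 10


@dataclass
class RegionFeatureVector:
    """The 57 named feature values for one (region, modality) pair.

    ``flags[name]`` is True where the value is a degenerate substitute (or the
    whole region fell below the minimum voxel count) and should be imputed
    from training data downstream.
    """

    region_id: int
    modality: str
    values: dict[str, float]
    flags: dict[str, bool] = field(repr=False)

    def __post_init__(self) -> None:
        if tuple(self.values) != FEATURE_NAMES:
            raise ValueError(f"feature vector must have the {N_FEATURES} catalogue features in order")

    def as_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in FEATURE_NAMES])

    def flag_array(self) -> np.ndarray:
        return np.array([self.flags[n] for n in FEATURE_NAMES], dtype=bool)


def extract_region_features(
    volume: np.ndarray,
    label_map: np.ndarray,
    region_id: int,
    modality: str = "",
    n_levels: int = 32,
    min_voxels: int = DEFAULT_MIN_VOXELS,
) -> RegionFeatureVector:
    """Extract the full 57-feature catalogue for one region of one volume.

    Intensity features come first (18), then texture (39), in catalogue
    order.  Deterministic; all values finite under the degeneracy policy.
    """
    q = quantize_region(volume, label_map, region_id, n_levels=n_levels)
    ivals, iflags = intensity_features(q)
    m = build_matrices(q)
    tvals, tflags = texture_features_cached(m)

    values = {**ivals, **tvals}
    flags = {**iflags, **tflags}
    if q.n_voxels < min_voxels:
        flags = {name: True for name in flags}
    values = {name: values[name] for name in FEATURE_NAMES}
    flags = {name: flags[name] for name in FEATURE_NAMES}
    return RegionFeatureVector(region_id=region_id, modality=modality, values=values, flags=flags)


def texture_features_cached(m):
    # thin indirection kept for profiling/monkeypatching in tests
    from cerebrad.features.texture import texture_features

    return texture_features(m)
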