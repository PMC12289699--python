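"""The fixed 57-feature catalogue: names, order, and block boundaries.

18 intensity features (12 on raw voxel intensities, 6 ``h_``-prefixed on the
quantized-level histogram) followed by 39 texture features: 8 GLCM, 13 GLRLM,
13 GLSZM, 5 NGTDM.  The order below is the canonical catalogue order used in
every feature vector and every exported table.
"""

from __future__ import annotations

INTENSITY_FEATURES: tuple[str, ...] = (
    "energy",
    "h_energy",
    "kurtosis",
    "max",
    "mean_absolute_deviation",
    "mean",
    "median",
    "min",
    "range",
    "root_mean_square",
    "skewness",
    "standard_deviation",
    "h_uniformity",
    "variance",
    "h_mean",
    "h_variance",
    "h_skewness",
    "h_kurtosis",
)

GLCM_FEATURES: tuple[str, ...] = (
    "glcm_energy",
    "glcm_contrast",
    "glcm_correlation",
    "glcm_homogeneity",
    "glcm_variance",
    "glcm_sum_average",
    "glcm_entropy",
    "glcm_dissimilarity",
)

GLRLM_FEATURES: tuple[str, ...] = (
    "glrlm_short_run_emphasis",
    "glrlm_long_run_emphasis",
    "glrlm_gray_level_nonuniformity",
    "glrlm_run_length_nonuniformity",
    "glrlm_run_percentage",
    "glrlm_low_gray_level_run_emphasis",
    "glrlm_high_gray_level_run_emphasis",
    "glrlm_short_run_low_gray_level_emphasis",
    "glrlm_short_run_high_gray_level_emphasis",
    "glrlm_long_run_low_gray_level_emphasis",
    "glrlm_long_run_high_gray_level_emphasis",
    "glrlm_gray_level_variance",
    "glrlm_run_length_variance",
)

GLSZM_FEATURES: tuple[str, ...] = (
    "glszm_small_zone_emphasis",
    "glszm_large_zone_emphasis",
    "glszm_gray_level_nonuniformity",
    "glszm_zone_size_nonuniformity",
    "glszm_zone_percentage",
    "glszm_low_gray_level_zone_emphasis",
    "glszm_high_gray_level_zone_emphasis",
    "glszm_small_zone_low_gray_level_emphasis",
    "glszm_small_zone_high_gray_level_emphasis",
    "glszm_large_zone_low_gray_level_emphasis",
    "glszm_large_zone_high_gray_level_emphasis",
    "glszm_gray_level_variance",
    "glszm_zone_size_variance",
)

NGTDM_FEATURES: tuple[str, ...] = (
    "ngtdm_coarseness",
    "ngtdm_contrast",
    "ngtdm_busyness",
    "ngtdm_complexity",
    "ngtdm_strength",
)

TEXTURE_FEATURES: tuple[str, ...] = (
    GLCM_FEATURES + GLRLM_FEATURES + GLSZM_FEATURES + NGTDM_FEATURES
)

#: All 57 features in canonical catalogue order.
FEATURE_NAMES: tuple[str, ...] = INTENSITY_FEATURES + TEXTURE_FEATURES

N_INTENSITY = len(INTENSITY_FEATURES)
N_TEXTURE = len(TEXTURE_FEATURES)
N_FEATURES = len(FEATURE_NAMES)

assert N_INTENSITY == 18 and N_TEXTURE == 39 and N_FEATURES == 57
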