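"""Gray-level quantization of a labelled region.

Equal-width binning between the region minimum and maximum into ``n_levels``
levels (default 32).  Quantization is min--max relative, so every feature
computed on the quantized domain is invariant to affine rescaling of the
input intensities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["QuantizedRegion", "EmptyRegionError", "quantize_region"]


class EmptyRegionError(ValueError):
    """Raised when a requested region contains no voxels."""

    def __init__(self, region_id):
        self.region_id = region_id
        super().__init__(f"region {region_id!r} contains no voxels")


@dataclass
class QuantizedRegion:
    """A region's raw intensities plus its quantized bounding-box map.

    ``quantized`` holds levels 1..n_levels inside the region and 0 outside
    (the out-of-region sentinel); ``mask`` marks in-region voxels of the
    bounding box.
    """

    voxel_values: np.ndarray
    quantized: np.ndarray
    mask: np.ndarray
    n_levels: int
    bin_edges: np.ndarray
    degenerate: bool  # constant-intensity region

    @property
    def n_voxels(self) -> int:
        return int(self.voxel_values.size)

    def histogram(self) -> np.ndarray:
        """Counts per level, length ``n_levels``."""
        return np.bincount(self.quantized[self.mask], minlength=self.n_levels + 1)[1:]


def quantize_region(
    volume: np.ndarray,
    label_map: np.ndarray,
    region_id: int,
    n_levels: int = 32,
) -> QuantizedRegion:
    """Quantize one region of a volume to ``n_levels`` equal-width gray levels.

    Ties at the region maximum are assigned to the top level; a constant
    region quantizes to level 1 everywhere with the ``degenerate`` flag set.

    Raises
    ------
    EmptyRegionError
        If the region has no voxels.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    if volume.shape != label_map.shape:
        raise ValueError("volume and label_map shapes differ")
    mask_full = label_map == region_id
    if not mask_full.any():
        raise EmptyRegionError(region_id)

    # Crop to the region bounding box.
    idx = np.argwhere(mask_full)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    mask = mask_full[box]
    vals_box = np.asarray(volume[box], dtype=float)
    values = vals_box[mask]

    vmin = float(values.min())
    vmax = float(values.max())
    quantized = np.zeros(mask.shape, dtype=np.int32)
    if vmax == vmin:
        quantized[mask] = 1
        edges = vmin + np.arange(n_levels + 1, dtype=float)
        return QuantizedRegion(values, quantized, mask, n_levels, edges, True)

    edges = np.linspace(vmin, vmax, n_levels + 1)
    width = (vmax - vmin) / n_levels
    levels = np.floor((vals_box - vmin) / width).astype(np.int32) + 1
    np.clip(levels, 1, n_levels, out=levels)
    quantized[mask] = levels[mask]
    return QuantizedRegion(values, quantized, mask, n_levels, edges, False)
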