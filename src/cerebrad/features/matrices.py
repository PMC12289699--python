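"""Texture matrices of a quantized region: GLCM, GLRLM, GLSZM, NGTDM.

All matrices are computed in 3-D.  Pairs and runs use the 13 unique
distance-1 offsets (half of the 26-neighbourhood); zones use 26-connectivity;
the NGTDM neighbourhood is the full 26-voxel shell with edge-corrected
neighbour means.  Out-of-region voxels never contribute to pairs, runs,
zones, or neighbourhood means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from cerebrad.features.quantization import QuantizedRegion

__all__ = ["TextureMatrices", "OFFSETS_13", "build_matrices"]

#: The 13 unique 3-D distance-1 offsets (first nonzero component positive).
OFFSETS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

assert len(OFFSETS_13) == 13


@dataclass
class TextureMatrices:
    """Count matrices plus the NGTDM triple for one quantized region."""

    glcm: np.ndarray  # (n_levels, n_levels) symmetric counts, summed over offsets
    glrlm: np.ndarray  # (n_levels, max_run) run counts, summed over directions
    glszm: np.ndarray  # (n_levels, max_zone) zone counts, 26-connectivity
    ngtdm_n: np.ndarray  # (n_levels,) occurrence counts n_i
    ngtdm_s: np.ndarray  # (n_levels,) summed absolute neighbourhood differences s_i
    n_levels: int
    n_voxels: int
    degenerate: bool  # single-voxel or constant region: all-texture-degenerate

    @property
    def glcm_normalized(self) -> np.ndarray:
        total = self.glcm.sum()
        return self.glcm / total if total > 0 else self.glcm.astype(float)

    @property
    def ngtdm_p(self) -> np.ndarray:
        total = self.ngtdm_n.sum()
        return self.ngtdm_n / total if total > 0 else self.ngtdm_n.astype(float)


def _shifted_views(a: np.ndarray, off: tuple[int, int, int]):
    """Views ``(a_src, a_dst)`` such that ``a_dst`` is ``a`` shifted by ``off``.

    Pairs ``(a_src[i], a_dst[i])`` enumerate all index pairs ``(v, v + off)``
    inside the array bounds.
    """
    src = []
    dst = []
    for d, n in zip(off, a.shape):
        if d >= 0:
            src.append(slice(0, n - d))
            dst.append(slice(d, n))
        else:
            src.append(slice(-d, n))
            dst.append(slice(0, n + d))
    return a[tuple(src)], a[tuple(dst)]


def _glcm(q: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    glcm = np.zeros((n_levels, n_levels), dtype=np.int64)
    for off in OFFSETS_13:
        qa, qb = _shifted_views(q, off)
        ma, mb = _shifted_views(mask, off)
        valid = ma & mb
        i = qa[valid] - 1
        j = qb[valid] - 1
        counts = np.bincount(i * n_levels + j, minlength=n_levels * n_levels)
        glcm += counts.reshape(n_levels, n_levels)
    return glcm + glcm.T  # symmetric: count each ordered pair both ways


def _glrlm(q: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Run-length counts along the 13 directions, summed.

    Run lengths are found by iterating a chain-length recurrence
    ``c[v] = c[v - d] + 1`` (vectorized over the whole box) to its fixed
    point; the run length is then read off at run-end voxels.
    """
    max_dim = int(np.ceil(np.sqrt(3) * max(q.shape))) + 1
    glrlm = np.zeros((n_levels, max_dim), dtype=np.int64)
    for off in OFFSETS_13:
        # same[v]: v and its predecessor v-off are both in-region with equal level
        pred = np.zeros_like(q)
        pred_m = np.zeros_like(mask)
        src, dst = _shifted_views(q, off)
        pred[tuple(_dst_slices(q.shape, off))] = src
        msrc, _ = _shifted_views(mask, off)
        pred_m[tuple(_dst_slices(mask.shape, off))] = msrc
        same = mask & pred_m & (q == pred)

        # chain length ending at each voxel
        c = mask.astype(np.int64)
        for _ in range(max(q.shape) - 1):
            c_pred = np.zeros_like(c)
            csrc, _ = _shifted_views(c, off)
            c_pred[tuple(_dst_slices(c.shape, off))] = csrc
            c_new = np.where(same, c_pred + 1, mask.astype(np.int64))
            if np.array_equal(c_new, c):
                break
            c = c_new

        # run ends: in-region voxels whose successor is not a continuation
        succ_same = np.zeros_like(same)
        ssrc, _ = _shifted_views(same, tuple(-d for d in off))
        succ_same[tuple(_dst_slices(same.shape, tuple(-d for d in off)))] = ssrc
        ends = mask & ~succ_same

        levels = q[ends] - 1
        lengths = c[ends]
        np.add.at(glrlm, (levels, lengths - 1), 1)
    return _trim_trailing(glrlm)


def _dst_slices(shape, off):
    out = []
    for d, n in zip(off, shape):
        if d >= 0:
            out.append(slice(d, n))
        else:
            out.append(slice(0, n + d))
    return out


def _trim_trailing(m: np.ndarray) -> np.ndarray:
    """Drop all-zero trailing columns (keep at least one)."""
    nz = np.nonzero(m.any(axis=0))[0]
    last = nz[-1] if nz.size else 0
    return m[:, : last + 1]


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def _glszm(q: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    sizes_per_level: dict[int, np.ndarray] = {}
    max_zone = 1
    for level in range(1, n_levels + 1):
        binary = q == level
        if not binary.any():
            continue
        labels, n_zones = ndimage.label(binary, structure=_STRUCT_26)
        sizes = np.bincount(labels[labels > 0])[1:]
        sizes_per_level[level] = sizes
        max_zone = max(max_zone, int(sizes.max()))
    glszm = np.zeros((n_levels, max_zone), dtype=np.int64)
    for level, sizes in sizes_per_level.items():
        counts = np.bincount(sizes, minlength=max_zone + 1)[1:]
        glszm[level - 1, :] = counts
    return glszm


_NGTDM_KERNEL = np.ones((3, 3, 3))
_NGTDM_KERNEL[1, 1, 1] = 0.0


def _ngtdm(q: np.ndarray, mask: np.ndarray, n_levels: int):
    vals = np.where(mask, q, 0).astype(float)
    nb_sum = ndimage.correlate(vals, _NGTDM_KERNEL, mode="constant", cval=0.0)
    nb_cnt = ndimage.correlate(mask.astype(float), _NGTDM_KERNEL, mode="constant", cval=0.0)
    valid = mask & (nb_cnt > 0.5)
    nb_mean = np.zeros_like(nb_sum)
    nb_mean[valid] = nb_sum[valid] / nb_cnt[valid]
    diff = np.abs(q - nb_mean)[valid]
    levels = q[valid] - 1
    n_i = np.bincount(levels, minlength=n_levels)
    s_i = np.bincount(levels, weights=diff, minlength=n_levels)
    return n_i.astype(np.int64), s_i


def build_matrices(q: QuantizedRegion) -> TextureMatrices:
    """Compute all four texture matrices of a quantized region.

    A single-voxel region yields validly shaped matrices with the
    all-texture-degenerate flag set (no voxel pairs exist).
    """
    qa = q.quantized
    mask = q.mask
    n = q.n_levels
    glcm = _glcm(qa, mask, n)
    glrlm = _glrlm(qa, mask, n)
    glszm = _glszm(qa, mask, n)
    n_i, s_i = _ngtdm(qa, mask, n)
    degenerate = q.degenerate or q.n_voxels < 2
    return TextureMatrices(
        glcm=glcm,
        glrlm=glrlm,
        glszm=glszm,
        ngtdm_n=n_i,
        ngtdm_s=s_i,
        n_levels=n,
        n_voxels=q.n_voxels,
        degenerate=degenerate,
    )
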