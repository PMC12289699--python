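"""Synthetic multimodal 3-D phantom cohorts with a cerebellar-style parcellation.

No imaging data accompany the study this pipeline emulates, so this module
stands in for it: three diagnostic groups (healthy controls, mild cognitive
impairment, Alzheimer's disease) whose regional image intensity and texture
differ by controllable effect sizes, three modality channels per subject
(T1, T2, FLAIR), and a voxel-aligned parcellation of an ellipsoidal
"cerebellum" into 26 contiguous regions.

The generative model per subject and modality is

    volume = gain_m * (baseline + mean_shift_g + subject_offset + noise)

where ``noise`` is white Gaussian noise smoothed with an isotropic Gaussian
filter of the group's ``smoothness`` scale and rescaled so its voxel-level
standard deviation equals the group's ``noise_sd``.  Group texture therefore
differs through the spatial correlation length, and group intensity through
the additive mean shift; ``subject_offset`` is a per-subject random intercept
shared across modalities.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "GroupEffect",
    "CohortSpec",
    "SubjectImageSet",
    "RegionSizeError",
    "generate_label_map",
    "generate_subject",
    "generate_cohort",
]

DEFAULT_GROUPS = ("HC", "MCI", "AD")
DEFAULT_MODALITIES = ("T1", "T2", "FLAIR")

#: Baseline tissue intensity, arbitrary units.
BASELINE = 100.0

#: Minimum voxels every parcel must receive.
MIN_REGION_VOXELS = 50


class RegionSizeError(ValueError):
    """Raised when the grid cannot give every region its minimum voxel count."""


@dataclass(frozen=True)
class GroupEffect:
    """Per-group effect sizes driving intensity and texture differences.

    Parameters
    ----------
    mean_shift
        Additive intensity offset per group (arbitrary units).  Defaults place
        HC at 0, MCI at +1 and AD at +2, i.e. a 2-noise-s.d. separation
        between the extreme groups.
    smoothness
        Gaussian smoothing scale (voxels) of the noise field per group; larger
        values give spatially smoother (coarser) texture.  Defaults give a
        1.5x contrast between AD and HC.
    noise_sd
        Voxel-level standard deviation of the smoothed noise per group.
    subject_sd
        Standard deviation of the per-subject random intercept (shared across
        modalities); between-subject biological variability.
    modality_gain
        Multiplicative factor per modality.
    """

    mean_shift: Mapping[str, float] = field(
        default_factory=lambda: {"HC": 0.0, "MCI": 1.0, "AD": 2.0}
    )
    smoothness: Mapping[str, float] = field(
        default_factory=lambda: {"HC": 1.0, "MCI": 1.25, "AD": 1.5}
    )
    noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {"HC": 1.0, "MCI": 1.0, "AD": 1.0}
    )
    subject_sd: float = 0.5
    modality_gain: Mapping[str, float] = field(
        default_factory=lambda: {"T1": 1.0, "T2": 0.9, "FLAIR": 1.1}
    )

    def validate(self, groups: Sequence[str], modalities: Sequence[str]) -> None:
        for g in groups:
            if g not in self.mean_shift:
                raise ValueError(f"mean_shift missing group {g!r}")
            if g not in self.smoothness:
                raise ValueError(f"smoothness missing group {g!r}")
            if self.smoothness[g] < 0:
                raise ValueError(f"smoothness must be >= 0 for group {g!r}")
            if g not in self.noise_sd:
                raise ValueError(f"noise_sd missing group {g!r}")
            if self.noise_sd[g] <= 0:
                raise ValueError(f"noise_sd must be > 0 for group {g!r}")
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be >= 0")
        for m in modalities:
            if m not in self.modality_gain:
                raise ValueError(f"modality_gain missing modality {m!r}")


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort; one spec = one reproducible world."""

    n_per_group: int = 30
    group_labels: tuple[str, ...] = DEFAULT_GROUPS
    grid_shape: tuple[int, int, int] = (64, 64, 32)
    voxel_size_mm: float = 1.0
    n_regions: int = 26
    modalities: tuple[str, ...] = DEFAULT_MODALITIES
    effect: GroupEffect = field(default_factory=GroupEffect)
    seed: int = 20240101

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        if len(set(self.group_labels)) != len(self.group_labels):
            raise ValueError("group labels must be distinct")
        if len(self.grid_shape) != 3 or any(s < 4 for s in self.grid_shape):
            raise ValueError("grid_shape must be three dimensions of >= 4 voxels")
        self.effect.validate(self.group_labels, self.modalities)


@dataclass
class SubjectImageSet:
    """Co-registered modality volumes plus the shared label map for one subject."""

    subject_id: str
    group: str
    volumes: dict[str, np.ndarray]
    label_map: np.ndarray

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.volumes.values()} | {self.label_map.shape}
        if len(shapes) != 1:
            raise ValueError("all volumes and the label map must share one shape")
        for name, v in self.volumes.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"volume {name!r} contains non-finite values")


def _ellipsoid_mask(shape: tuple[int, int, int]) -> np.ndarray:
    """Foreground ellipsoid inscribed in the grid (semi-axes at 45% of each dim)."""
    coords = np.indices(shape).astype(float)
    centre = [(s - 1) / 2.0 for s in shape]
    semi = [0.45 * s for s in shape]
    r2 = sum(((c - c0) / a) ** 2 for c, c0, a in zip(coords, centre, semi))
    return r2 <= 1.0


def generate_label_map(spec: CohortSpec) -> np.ndarray:
    """Partition an ellipsoidal foreground into ``n_regions`` contiguous parcels.

    Seed points are drawn inside the foreground with a minimum-separation
    rejection rule; every foreground voxel is then assigned to its nearest
    seed (Euclidean), which yields convex, hence contiguous, parcels.
    Deterministic for a given ``spec.seed``.

    Raises
    ------
    RegionSizeError
        If any region would receive fewer than 50 voxels.
    """
    rng = np.random.default_rng(spec.seed)
    mask = _ellipsoid_mask(spec.grid_shape)
    fg = np.argwhere(mask)
    if fg.shape[0] < MIN_REGION_VOXELS * spec.n_regions:
        raise RegionSizeError(
            f"grid {spec.grid_shape} has {fg.shape[0]} foreground voxels; "
            f"cannot give {spec.n_regions} regions >= {MIN_REGION_VOXELS} voxels each"
        )
    # Poisson-disk-ish seeding: enforce pairwise separation of half the
    # nominal parcel diameter so no Voronoi cell collapses.
    min_sep = 0.5 * (fg.shape[0] / spec.n_regions) ** (1.0 / 3.0)
    seeds: list[np.ndarray] = []
    order = rng.permutation(fg.shape[0])
    for idx in order:
        p = fg[idx]
        if all(np.linalg.norm(p - q) >= min_sep for q in seeds):
            seeds.append(p)
        if len(seeds) == spec.n_regions:
            break
    if len(seeds) < spec.n_regions:
        # Separation too strict for this grid; fall back to plain sampling.
        extra = fg[rng.choice(fg.shape[0], spec.n_regions - len(seeds), replace=False)]
        seeds.extend(extra)
    seed_arr = np.asarray(seeds, dtype=float)

    d2 = ((fg[:, None, :] - seed_arr[None, :, :]) ** 2).sum(axis=2)
    assignment = np.argmin(d2, axis=1) + 1

    label_map = np.zeros(spec.grid_shape, dtype=np.int16)
    label_map[tuple(fg.T)] = assignment

    counts = np.bincount(assignment, minlength=spec.n_regions + 1)
    for region in range(1, spec.n_regions + 1):
        if counts[region] < MIN_REGION_VOXELS:
            raise RegionSizeError(
                f"region {region} received {counts[region]} voxels "
                f"(< {MIN_REGION_VOXELS}); grid {spec.grid_shape} too small for "
                f"{spec.n_regions} regions"
            )
    return label_map


def _smoothed_noise(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    sigma: float,
    sd: float,
) -> np.ndarray:
    """White Gaussian noise, Gaussian-smoothed, rescaled to voxel s.d. ``sd``.

    The rescale factor is the L2 norm of the effective discrete smoothing
    kernel (impulse response), so the interior-voxel marginal s.d. equals
    ``sd`` exactly regardless of ``sigma``.
    """
    white = rng.standard_normal(shape)
    if sigma <= 0:
        return sd * white
    smoothed = gaussian_filter(white, sigma=sigma, mode="reflect")
    half = int(np.ceil(4 * sigma)) + 1
    impulse = np.zeros((2 * half + 1,) * 3)
    impulse[half, half, half] = 1.0
    kernel = gaussian_filter(impulse, sigma=sigma, mode="constant")
    norm = float(np.sqrt((kernel**2).sum()))
    return sd * smoothed / norm


def generate_subject(
    spec: CohortSpec,
    group: str,
    subject_seed: int,
    label_map: np.ndarray | None = None,
    subject_id: str | None = None,
) -> SubjectImageSet:
    """Simulate one subject's co-registered modality volumes.

    Reproducible from ``(spec.seed, subject_seed)``.  The label map is shared
    across the cohort; pass it in to avoid regenerating it per subject.
    """
    if group not in spec.group_labels:
        raise ValueError(f"unknown group label {group!r}; expected one of {spec.group_labels}")
    if label_map is None:
        label_map = generate_label_map(spec)
    eff = spec.effect
    rng = np.random.default_rng([spec.seed, subject_seed])
    subject_offset = rng.normal(0.0, eff.subject_sd) if eff.subject_sd > 0 else 0.0
    volumes: dict[str, np.ndarray] = {}
    for modality in spec.modalities:
        noise = _smoothed_noise(
            rng, spec.grid_shape, eff.smoothness[group], eff.noise_sd[group]
        )
        vol = eff.modality_gain[modality] * (
            BASELINE + eff.mean_shift[group] + subject_offset + noise
        )
        volumes[modality] = vol
    if subject_id is None:
        subject_id = f"{group}_{subject_seed}"
    return SubjectImageSet(subject_id=subject_id, group=group, volumes=volumes, label_map=label_map)


def iter_cohort(spec: CohortSpec, label_map: np.ndarray | None = None):
    """Yield ``(subject_index, subject_seed, SubjectImageSet)`` in manifest order.

    Subjects are ordered group-by-group in ``spec.group_labels`` order; the
    per-subject seed is ``spec.seed + index`` (recorded in the manifest).
    """
    if label_map is None:
        label_map = generate_label_map(spec)
    index = 0
    for group in spec.group_labels:
        for k in range(spec.n_per_group):
            subject_seed = spec.seed + index
            sid = f"sub-{index:03d}_{group}"
            yield index, subject_seed, generate_subject(
                spec, group, subject_seed, label_map=label_map, subject_id=sid
            )
            index += 1


def generate_cohort(spec: CohortSpec, out_dir: str | Path) -> pd.DataFrame:
    """Write the full cohort as NIfTI volumes plus a manifest CSV.

    Returns the manifest table (subject_id, group, one path column per
    modality, label_map path, seed), with ``n_per_group x n_groups`` rows in
    deterministic order.
    """
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag([spec.voxel_size_mm] * 3 + [1.0])

    label_map = generate_label_map(spec)
    label_path = out_dir / "label_map.nii.gz"
    nib.save(nib.Nifti1Image(label_map.astype(np.int16), affine), label_path)

    rows = []
    for _, subject_seed, subject in iter_cohort(spec, label_map=label_map):
        row: dict[str, object] = {"subject_id": subject.subject_id, "group": subject.group}
        for modality in spec.modalities:
            p = out_dir / f"{subject.subject_id}_{modality}.nii.gz"
            nib.save(nib.Nifti1Image(subject.volumes[modality].astype(np.float32), affine), p)
            row[modality] = str(p)
        row["label_map"] = str(label_path)
        row["seed"] = subject_seed
        rows.append(row)

    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def spec_to_dict(spec: CohortSpec) -> dict:
    """JSON-serializable description of a spec (provenance sidecars)."""
    d = dataclasses.asdict(spec)
    d["effect"] = {k: (dict(v) if isinstance(v, Mapping) else v) for k, v in d["effect"].items()}
    return d
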