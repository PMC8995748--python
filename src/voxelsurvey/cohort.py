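"""Synthetic two-group gray-matter-density (GMD) cohorts.

Voxel-based morphometry reduces a structural MRI to a 3D map of local
gray-matter density per voxel.  Real cohorts of such maps (e.g. ADNI) are
access-restricted, so this module generates seeded surrogate cohorts: a
smooth baseline density field shared by all subjects, a group-specific
density *loss* planted at a chosen set of "informative" voxels in the
disease group, additive Gaussian noise, and clipping to the valid density
range [0, 1].  The planted-voxel mask is emitted as ground truth so that
feature-recovery experiments can be scored.

Label convention: disease = -1, healthy control = +1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

DISEASE = -1
CONTROL = +1

#: Baseline density fields are rescaled into this range so that a shift of
#: ~0.3 rarely clips against [0, 1].
BASELINE_RANGE = (0.3, 0.7)


@dataclass(frozen=True)
class GmdMap:
    """One subject's 3D gray-matter-density map.

    Attributes
    ----------
    subject_id : str
        Unique subject identifier.
    group : int
        ``DISEASE`` (-1) or ``CONTROL`` (+1).
    data : numpy.ndarray
        3D array of densities in [0, 1].
    """

    subject_id: str
    group: int
    data: np.ndarray

    def __post_init__(self):
        if self.group not in (DISEASE, CONTROL):
            raise ValueError(f"group must be {DISEASE} or {CONTROL}, got {self.group}")
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3D, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")


@dataclass
class GmdCohort:
    """A two-group cohort of GMD maps plus (synthetic-only) ground truth.

    Attributes
    ----------
    maps : list of GmdMap
        All subjects, disease and control.
    truth_mask : numpy.ndarray or None
        Boolean 3D mask of planted informative voxels; ``None`` for real data.
    gen_params : dict
        Record of the generator parameters (empty for loaded real data).
    """

    maps: list[GmdMap]
    truth_mask: np.ndarray | None = None
    gen_params: dict = field(default_factory=dict)

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self.maps[0].data.shape)

    @property
    def n_subjects(self) -> int:
        return len(self.maps)

    @property
    def labels(self) -> np.ndarray:
        return np.array([m.group for m in self.maps], dtype=int)

    def __post_init__(self):
        if not self.maps:
            raise ValueError("cohort must contain at least one map")
        dims = self.maps[0].data.shape
        for m in self.maps:
            if m.data.shape != dims:
                raise ValueError(
                    f"map {m.subject_id} has dims {m.data.shape}, expected {dims}"
                )
        if self.truth_mask is not None and tuple(self.truth_mask.shape) != tuple(dims):
            raise ValueError("truth_mask dims do not match map dims")


def _smooth_baseline(dims, smoothness, rng) -> np.ndarray:
    """Smoothed uniform-random field rescaled into BASELINE_RANGE."""
    raw = rng.uniform(size=dims)
    smooth = gaussian_filter(raw, sigma=smoothness, mode="nearest")
    lo, hi = BASELINE_RANGE
    ptp = smooth.max() - smooth.min()
    if ptp == 0:  # pathological (e.g. huge smoothness) — flat mid-range field
        return np.full(dims, (lo + hi) / 2.0)
    return lo + (hi - lo) * (smooth - smooth.min()) / ptp


def _grow_blob(dims, n_voxels, rng) -> np.ndarray:
    """Contiguous informative region: random seed voxel grown by random
    nearest-neighbour accretion (6-connectivity)."""
    mask = np.zeros(dims, dtype=bool)
    start = tuple(rng.integers(0, d) for d in dims)
    mask[start] = True
    frontier = set()

    def neighbours(idx):
        for axis in range(3):
            for step in (-1, 1):
                nxt = list(idx)
                nxt[axis] += step
                if 0 <= nxt[axis] < dims[axis]:
                    yield tuple(nxt)

    frontier.update(n for n in neighbours(start) if not mask[n])
    while mask.sum() < n_voxels:
        if not frontier:
            raise RuntimeError("blob growth exhausted the volume")
        choice = sorted(frontier)[rng.integers(0, len(frontier))]
        frontier.discard(choice)
        mask[choice] = True
        frontier.update(n for n in neighbours(choice) if not mask[n])
    return mask


def generate_cohort(
    n_disease: int = 60,
    n_control: int = 60,
    dims: tuple[int, int, int] = (10, 12, 10),
    n_informative: int = 40,
    effect_size: float = 0.3,
    noise_sd: float = 0.05,
    seed: int = 0,
    baseline_smoothness: float = 2.0,
    informative_layout: str = "blob",
) -> GmdCohort:
    """Generate a seeded two-group cohort with planted informative voxels.

    Each map is ``clip(baseline + shift + noise, 0, 1)`` where the baseline
    is one smooth field shared by every subject, the shift is
    ``-effect_size`` at informative voxels for disease subjects (density
    loss) and zero elsewhere, and the noise is i.i.d. Gaussian with standard
    deviation ``noise_sd``.

    Parameters
    ----------
    n_disease, n_control : int
        Subjects per group.
    dims : tuple of int
        Map dimensions (dx, dy, dz), each >= 1.
    n_informative : int
        Number of planted voxels; must not exceed ``prod(dims)``.
    effect_size : float
        Density reduction applied to the disease group at planted voxels.
    noise_sd : float
        Per-voxel Gaussian noise standard deviation (>= 0).
    seed : int
        Reproducibility seed; identical parameters reproduce the cohort
        bit-for-bit.
    baseline_smoothness : float
        Gaussian smoothing sigma (in voxels) of the baseline field.
    informative_layout : {"blob", "scattered"}
        Planted voxels as one contiguous blob (default; atrophy is
        spatially contiguous) or scattered uniformly at random.

    Returns
    -------
    GmdCohort
    """
    dims = tuple(int(d) for d in dims)
    if len(dims) != 3 or any(d < 1 for d in dims):
        raise ValueError(f"dims must be three positive integers, got {dims}")
    n_voxels = int(np.prod(dims))
    if n_informative > n_voxels:
        raise ValueError(
            f"n_informative ({n_informative}) exceeds voxel count ({n_voxels})"
        )
    if n_informative < 0:
        raise ValueError(f"n_informative must be >= 0, got {n_informative}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    if n_disease < 1 or n_control < 1:
        raise ValueError(
            f"need at least one subject per group, got n_disease={n_disease}, "
            f"n_control={n_control}"
        )
    if informative_layout not in ("blob", "scattered"):
        raise ValueError(f"unknown informative_layout {informative_layout!r}")

    # Independent streams so that changing effect_size does not change the
    # baseline, mask or noise draws (matched-seed comparisons rely on this).
    ss = np.random.SeedSequence(seed)
    rng_base, rng_mask, rng_noise = (np.random.default_rng(c) for c in ss.spawn(3))

    baseline = _smooth_baseline(dims, baseline_smoothness, rng_base)

    mask = np.zeros(dims, dtype=bool)
    if n_informative > 0:
        if informative_layout == "blob":
            mask = _grow_blob(dims, n_informative, rng_mask)
        else:
            flat = rng_mask.choice(n_voxels, size=n_informative, replace=False)
            mask.flat[flat] = True

    maps = []
    for g, n_g, tag in ((DISEASE, n_disease, "dis"), (CONTROL, n_control, "ctl")):
        shift = -effect_size * mask if g == DISEASE else 0.0
        for i in range(n_g):
            noise = rng_noise.normal(0.0, noise_sd, size=dims) if noise_sd > 0 else 0.0
            data = np.clip(baseline + shift + noise, 0.0, 1.0)
            maps.append(GmdMap(subject_id=f"{tag}{i:04d}", group=g, data=data))

    gen_params = dict(
        n_disease=n_disease,
        n_control=n_control,
        dims=dims,
        n_informative=n_informative,
        effect_size=effect_size,
        noise_sd=noise_sd,
        baseline_smoothness=baseline_smoothness,
        informative_layout=informative_layout,
        seed=seed,
    )
    return GmdCohort(maps=maps, truth_mask=mask, gen_params=gen_params)


# ---------------------------------------------------------------------------
# Persistence: one NIfTI per subject + subjects.csv + truth mask + manifest.


def save_cohort(cohort: GmdCohort, path: str | Path) -> Path:
    """Write a cohort to ``path`` and return the manifest path.

    Layout: ``sub-<id>.nii.gz`` per subject, ``subjects.csv`` with columns
    (subject_id, group), ``truth_mask.nii.gz`` if present, and
    ``manifest.json`` recording the generator parameters and file list.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    files = {}
    for m in cohort.maps:
        fname = f"sub-{m.subject_id}.nii.gz"
        nib.save(nib.Nifti1Image(m.data.astype(np.float64), affine), path / fname)
        files[m.subject_id] = fname
    pd.DataFrame(
        {"subject_id": [m.subject_id for m in cohort.maps],
         "group": [m.group for m in cohort.maps]}
    ).to_csv(path / "subjects.csv", index=False)
    mask_file = None
    if cohort.truth_mask is not None:
        mask_file = "truth_mask.nii.gz"
        nib.save(
            nib.Nifti1Image(cohort.truth_mask.astype(np.uint8), affine),
            path / mask_file,
        )
    manifest = {
        "format": "voxelsurvey-cohort-v1",
        "dims": list(cohort.dims),
        "flatten_order": "C",
        "files": files,
        "truth_mask": mask_file,
        "gen_params": cohort.gen_params,
    }
    manifest_path = path / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def load_cohort(path: str | Path) -> GmdCohort:
    """Load a cohort written by :func:`save_cohort`.

    Raises
    ------
    FileNotFoundError
        Missing manifest or a listed map file (the offending file is named).
    ValueError
        Dimension mismatch among files (the offending file is named).
    """
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"missing manifest: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    dims = tuple(manifest["dims"])

    subjects = pd.read_csv(path / "subjects.csv")
    maps = []
    for _, row in subjects.iterrows():
        sid = str(row["subject_id"])
        fname = manifest["files"][sid]
        fpath = path / fname
        if not fpath.exists():
            raise FileNotFoundError(f"missing map file listed in manifest: {fpath}")
        data = np.asarray(nib.load(fpath).get_fdata(), dtype=np.float64)
        if data.shape != dims:
            raise ValueError(
                f"dimension mismatch in {fname}: {data.shape} != {dims}"
            )
        maps.append(GmdMap(subject_id=sid, group=int(row["group"]), data=data))

    mask = None
    if manifest.get("truth_mask"):
        mpath = path / manifest["truth_mask"]
        if not mpath.exists():
            raise FileNotFoundError(f"missing truth mask listed in manifest: {mpath}")
        mask = np.asarray(nib.load(mpath).get_fdata()) > 0.5
        if mask.shape != dims:
            raise ValueError(f"dimension mismatch in truth mask: {mask.shape} != {dims}")

    return GmdCohort(maps=maps, truth_mask=mask, gen_params=manifest.get("gen_params", {}))
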