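"""Volume/mask I/O, VOI handling and gray-level quantization.

Volumes are plain 3D scalar grids (HU-like units) indexed ``(i, j, k)``
with axial slices along the last axis. A case is four contrast phases of
the same tumor (arterial early/mid/late and the hepatobiliary phase)
sharing one binary volume-of-interest mask. Texture matrices require
discrete gray levels, so the in-mask intensity range is re-binned into
``G`` equal-width levels before any matrix is built.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

#: Fixed acquisition order of the four contrast phases.
PHASE_ORDER = ("arterial_early", "arterial_mid", "arterial_late", "hepatobiliary")

RECIST_CODES = ("CR", "PR", "SD", "PD")


class ShapeMismatchError(ValueError):
    """A phase volume and its mask (or sibling phases) disagree in shape."""


class MissingPhaseError(ValueError):
    """A case does not provide all four required contrast phases."""


class EmptyMaskError(ValueError):
    """The VOI mask contains no foreground voxel."""


@dataclasses.dataclass(frozen=True)
class PhaseVolume:
    """One 3D intensity grid for one contrast phase of one case."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    phase_id: str

    def __post_init__(self):
        vox = np.asarray(self.voxels, dtype=float)
        if vox.ndim != 3 or min(vox.shape) < 1:
            raise ValueError("voxels must be a 3D grid with size >= 1 per axis")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three strictly positive components")
        if self.phase_id not in PHASE_ORDER:
            raise ValueError(f"unknown phase_id {self.phase_id!r}; expected one of {PHASE_ORDER}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclasses.dataclass(frozen=True)
class VOIMask:
    """Binary tumor mask aligned with its phase volumes."""

    mask: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.mask)
        if m.ndim != 3:
            raise ValueError("mask must be 3D")
        object.__setattr__(self, "mask", m != 0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclasses.dataclass(frozen=True)
class QuantizedVOI:
    """In-mask intensities discretized to integer gray levels 1..G.

    ``levels`` is 0 outside the mask; every in-mask voxel carries exactly
    one level in ``1..G``. ``bin_edges`` is the strictly increasing
    intensity partition that produced the levels.
    """

    levels: np.ndarray
    mask: np.ndarray
    G: int
    bin_edges: np.ndarray


@dataclasses.dataclass
class VOIStack:
    """A case: four aligned phase volumes, one mask, and a RECIST label."""

    case_id: str
    phases: dict[str, PhaseVolume]
    mask: VOIMask
    recist: str

    def __post_init__(self):
        missing = [p for p in PHASE_ORDER if p not in self.phases]
        if missing:
            raise MissingPhaseError(
                f"case {self.case_id!r} is missing phases {missing}; required: {list(PHASE_ORDER)}"
            )
        for pid, vol in self.phases.items():
            if vol.shape != self.mask.shape:
                raise ShapeMismatchError(
                    f"case {self.case_id!r}: phase {pid!r} shape {vol.shape} != mask shape {self.mask.shape}"
                )
        if self.recist not in RECIST_CODES:
            raise ValueError(f"unknown RECIST code {self.recist!r}; expected one of {RECIST_CODES}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape


def quantize(volume: PhaseVolume, mask: VOIMask, G: int = 64) -> QuantizedVOI:
    """Equal-width re-binning of the in-mask intensity range into G levels.

    Bins span ``[in-mask min, in-mask max]``; a constant region (zero
    range) maps entirely to level 1 so downstream features stay defined
    (entropy 0, energy 1).
    """
    if G < 2:
        raise ValueError(f"G must be >= 2, got {G}")
    if volume.shape != mask.shape:
        raise ShapeMismatchError(f"volume shape {volume.shape} != mask shape {mask.shape}")
    m = mask.mask
    if not m.any():
        raise EmptyMaskError("cannot quantize an empty VOI")
    vals = volume.voxels[m]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(volume.shape, dtype=np.int32)
    if hi == lo:
        levels[m] = 1
        bin_edges = np.array([lo, lo + 1.0])
    else:
        bin_edges = np.linspace(lo, hi, G + 1)
        scaled = (volume.voxels[m] - lo) / (hi - lo) * G
        levels[m] = np.clip(np.floor(scaled).astype(np.int32) + 1, 1, G)
    return QuantizedVOI(levels=levels, mask=m, G=int(G), bin_edges=bin_edges)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def save_volume(path: str | Path, voxels: np.ndarray, spacing: Sequence[float]) -> None:
    """Write a 3D grid to NIfTI with the given voxel spacing (mm)."""
    affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    nib.save(nib.Nifti1Image(np.asarray(voxels), affine), str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj, dtype=np.float64), spacing


def load_case(
    case_id: str,
    phase_paths: Mapping[str, str | Path],
    mask_path: str | Path,
    recist: str,
) -> VOIStack:
    """Load one case's four phase volumes plus mask from NIfTI files.

    ``phase_paths`` maps phase_id -> file; any nonzero voxel of the mask
    file counts as foreground.
    """
    missing = [p for p in PHASE_ORDER if p not in phase_paths]
    if missing:
        raise MissingPhaseError(
            f"case {case_id!r} manifest is missing phases {missing}; required: {list(PHASE_ORDER)}"
        )
    mask_vox, _ = load_volume(mask_path)
    mask = VOIMask(mask_vox)
    phases = {}
    for pid in PHASE_ORDER:
        vox, spacing = load_volume(phase_paths[pid])
        if vox.shape != mask.shape:
            raise ShapeMismatchError(
                f"case {case_id!r}: phase {pid!r} shape {vox.shape} != mask shape {mask.shape}"
            )
        phases[pid] = PhaseVolume(vox, spacing, pid)
    return VOIStack(case_id=case_id, phases=phases, mask=mask, recist=recist)


def load_manifest(manifest_csv: str | Path) -> list[VOIStack]:
    """Load a cohort from a manifest CSV.

    Columns: case_id, phase_id, volume_path, mask_path, recist. Paths are
    resolved relative to the manifest's directory if not absolute.
    """
    manifest_csv = Path(manifest_csv)
    df = pd.read_csv(manifest_csv)
    required = {"case_id", "phase_id", "volume_path", "mask_path", "recist"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    root = manifest_csv.parent

    def _resolve(p: str) -> Path:
        p = Path(p)
        return p if p.is_absolute() else root / p

    stacks = []
    for case_id, grp in df.groupby("case_id", sort=True):
        phase_paths = {row.phase_id: _resolve(row.volume_path) for row in grp.itertuples()}
        mask_path = _resolve(grp["mask_path"].iloc[0])
        recist = str(grp["recist"].iloc[0])
        stacks.append(load_case(str(case_id), phase_paths, mask_path, recist))
    return stacks


def crop_to_bbox(
    levels: np.ndarray, mask: np.ndarray, margin: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Crop a level grid and mask to the mask's bounding box (+margin)."""
    idx = np.nonzero(mask)
    slices = tuple(
        slice(max(int(a.min()) - margin, 0), min(int(a.max()) + margin + 1, n))
        for a, n in zip(idx, mask.shape)
    )
    return levels[slices], mask[slices]
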