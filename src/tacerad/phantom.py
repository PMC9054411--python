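"""Synthetic multiphase tumor phantoms with class-dependent texture.

The generator emulates a balanced two-class treatment-response cohort
(default 24 responders vs. 24 non-responders) of 4-phase contrast-enhanced
volumes. Each case is an ellipsoidal tumor mask inside a cubic grid; each
phase volume is a class- and phase-dependent mean intensity plus spatially
correlated Gaussian texture (Gaussian-filtered white noise rescaled to a
target standard deviation). The two classes are separated by construction
through three planted mechanisms:

* enhancement dynamics — responders wash in and out strongly across the
  four phases, non-responders stay nearly flat, so inter-phase change-rate
  features carry signal;
* heterogeneity — the non-responder class has a larger noise amplitude
  (sigma multiplier), moving variance/range/MAD and matrix features;
* zone structure — the non-responder class has a longer spatial
  correlation length, i.e. smoother, blobbier texture, moving GLCM
  contrast/entropy and zone-size features.

Responder cases are labelled CR or PR, non-responders SD or PD, at random
but consistently with the class. Everything is reproducible from the seed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging_io import PHASE_ORDER, PhaseVolume, VOIMask, VOIStack, save_volume


@dataclasses.dataclass
class ClassParams:
    """Per-class generative parameters."""

    mu_profile: tuple[float, float, float, float]  # mean intensity per phase
    sigma: float  # texture noise std (intensity units)
    correlation_length: float  # Gaussian smoothing sigma (voxels)
    recist_codes: tuple[str, ...]


@dataclasses.dataclass
class PhantomConfig:
    """Cohort geometry and class-separation parameters.

    Defaults give a 24-vs-24 cohort on a 48-cubed 1 mm grid. The responder
    class enhances strongly (arterial wash-in then wash-out), the
    non-responder class is hypovascular and nearly flat; non-responders are
    twice as heterogeneous (sigma) with a ~2x longer texture correlation
    length.
    """

    n_per_class: int = 24
    grid: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    radius_range_mm: tuple[float, float] = (8.0, 15.0)
    responder: ClassParams = dataclasses.field(
        default_factory=lambda: ClassParams(
            mu_profile=(100.0, 165.0, 130.0, 108.0),
            sigma=12.0,
            correlation_length=1.0,
            recist_codes=("CR", "PR"),
        )
    )
    non_responder: ClassParams = dataclasses.field(
        default_factory=lambda: ClassParams(
            mu_profile=(100.0, 118.0, 112.0, 106.0),
            sigma=24.0,
            correlation_length=2.2,
            recist_codes=("SD", "PD"),
        )
    )
    profile_jitter: float = 0.05  # per-case multiplicative sd on mu profile
    sigma_jitter: float = 0.10  # per-case multiplicative sd on sigma
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class < 2:
            raise ValueError("need at least 2 cases per class")
        rad_vox = self.radius_range_mm[1] / min(self.spacing)
        if 2 * rad_vox + 2 > min(self.grid):
            raise ValueError("largest tumor radius does not fit inside the grid")


def _ellipsoid_mask(grid, center, radii_vox) -> np.ndarray:
    coords = np.indices(grid).astype(float)
    u = sum(((coords[ax] - center[ax]) / radii_vox[ax]) ** 2 for ax in range(3))
    return u <= 1.0


def _correlated_noise(rng: np.random.Generator, grid, corr_len: float) -> np.ndarray:
    """Unit-variance spatially correlated Gaussian field."""
    white = rng.standard_normal(grid)
    field = ndimage.gaussian_filter(white, sigma=corr_len, mode="wrap")
    return field / field.std()


def _one_case(rng: np.random.Generator, case_id: str, cfg: PhantomConfig, cls: ClassParams) -> VOIStack:
    grid = cfg.grid
    lo, hi = cfg.radius_range_mm
    radii_mm = rng.uniform(lo, hi, size=3)
    radii_vox = radii_mm / np.asarray(cfg.spacing)
    center = np.asarray(grid) / 2.0 + rng.uniform(-2, 2, size=3)
    mask = _ellipsoid_mask(grid, center, radii_vox)
    profile_scale = 1.0 + cfg.profile_jitter * rng.standard_normal()
    sigma = cls.sigma * max(0.2, 1.0 + cfg.sigma_jitter * rng.standard_normal())
    phases = {}
    for p_idx, pid in enumerate(PHASE_ORDER):
        mu = cls.mu_profile[p_idx] * profile_scale
        field = _correlated_noise(rng, grid, cls.correlation_length)
        vox = mu + sigma * field
        phases[pid] = PhaseVolume(vox, cfg.spacing, pid)
    recist = cls.recist_codes[rng.integers(0, len(cls.recist_codes))]
    return VOIStack(case_id=case_id, phases=phases, mask=VOIMask(mask), recist=recist)


def generate_cohort(cfg: PhantomConfig) -> tuple[list[VOIStack], pd.DataFrame]:
    """Generate the full phantom cohort and its ground-truth table.

    Returns the list of cases (responders first) and a table with columns
    case_id, group (+1 responder / -1 non-responder), recist, and the
    per-case generative parameters. Identical config -> identical cohort.
    """
    rng = np.random.default_rng(cfg.seed)
    stacks: list[VOIStack] = []
    rows = []
    for cls, cls_params, group in (
        ("resp", cfg.responder, 1),
        ("nonresp", cfg.non_responder, -1),
    ):
        for i in range(cfg.n_per_class):
            case_id = f"{cls}_{i:03d}"
            stack = _one_case(rng, case_id, cfg, cls_params)
            stacks.append(stack)
            rows.append({
                "case_id": case_id,
                "group": group,
                "recist": stack.recist,
                "n_mask_voxels": stack.mask.n_voxels,
            })
    return stacks, pd.DataFrame(rows)


def write_cohort(cfg: PhantomConfig, outdir: str | Path) -> Path:
    """Write the cohort as NIfTI volumes + manifest CSV + ground truth CSV.

    Returns the manifest path (the layout ``imaging_io.load_manifest``
    reads back).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stacks, truth = generate_cohort(cfg)
    rows = []
    for stack in stacks:
        mask_path = f"{stack.case_id}_mask.nii.gz"
        save_volume(outdir / mask_path, stack.mask.mask.astype(np.uint8), cfg.spacing)
        for pid, vol in stack.phases.items():
            vol_path = f"{stack.case_id}_{pid}.nii.gz"
            save_volume(outdir / vol_path, vol.voxels, cfg.spacing)
            rows.append({
                "case_id": stack.case_id, "phase_id": pid,
                "volume_path": vol_path, "mask_path": mask_path,
                "recist": stack.recist,
            })
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    truth.to_csv(outdir / "ground_truth.csv", index=False)
    return manifest


def generate_feature_table(
    n: int = 48,
    informative: int = 5,
    noise: int = 200,
    effect: float = 1.0,
    n_duplicates: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Tabular simulation for selection/SVM tests without image extraction.

    Informative columns are class-shifted normals (class means separated
    by ``effect`` standard deviations); noise columns are N(0,1). The
    first ``n_duplicates`` informative columns are duplicated verbatim
    (named ``dup_*``) to exercise the correlation filter. Labels are
    balanced +1/-1.
    """
    if informative + noise < 1:
        raise ValueError("need at least one column")
    if n < 4:
        raise ValueError("need n >= 4")
    rng = np.random.default_rng(seed)
    y = np.array([1] * (n // 2) + [-1] * (n - n // 2))
    cols = {}
    for j in range(informative):
        cols[f"info_{j:03d}"] = rng.standard_normal(n) + effect * (y > 0) - effect / 2.0
    for j in range(noise):
        cols[f"noise_{j:03d}"] = rng.standard_normal(n)
    X = pd.DataFrame(cols)
    for j in range(min(n_duplicates, informative)):
        X[f"dup_{j:03d}"] = X[f"info_{j:03d}"].to_numpy().copy()
    return X, y
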