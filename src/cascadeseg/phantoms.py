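"""Synthetic multi-modal brain-tumor phantoms.

Generates BraTS-layout cases — four co-registered MRI contrasts (FLAIR, T1,
T1ce, T2) plus an integer label volume with values {0, 1, 2, 4} — without any
download.  Tumors are nested concentric ellipsoids inside a spherical "brain":
an edema shell (label 2) around a necrotic rim (label 1) around an enhancing
nucleus (label 4), which guarantees the ET ⊆ TC ⊆ WT nesting the evaluation
regions assume.  Intensities are piecewise-constant compartment means plus
additive Gaussian noise, clipped at zero; background outside the brain is
exactly zero, matching skull-stripped data.

Not modelled: MRI physics, bias fields, multi-focal tumors.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np

MODALITIES = ("flair", "t1", "t1ce", "t2")
COMPARTMENTS = ("brain", "edema", "necrotic", "enhancing")

#: Default per-modality, per-compartment mean intensities.  Chosen so that the
#: qualitative radiology holds: edema is brightest on FLAIR/T2, the enhancing
#: rim is brightest on T1ce, necrosis is dark on T1/T1ce.
DEFAULT_CONTRAST: dict[str, dict[str, float]] = {
    "flair": {"brain": 100.0, "edema": 220.0, "necrotic": 150.0, "enhancing": 160.0},
    "t1":    {"brain": 120.0, "edema": 90.0,  "necrotic": 50.0,  "enhancing": 140.0},
    "t1ce":  {"brain": 120.0, "edema": 95.0,  "necrotic": 55.0,  "enhancing": 240.0},
    "t2":    {"brain": 90.0,  "edema": 200.0, "necrotic": 170.0, "enhancing": 130.0},
}


@dataclasses.dataclass
class PhantomSpec:
    """Full description of one synthetic case; deterministic given ``seed``."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    brain_radius_frac: float = 0.42
    tumor_center: tuple[float, float, float] | None = None
    radii: tuple[float, float, float] = (12.0, 8.0, 4.0)
    modality_contrast: dict[str, dict[str, float]] = dataclasses.field(
        default_factory=lambda: {m: dict(v) for m, v in DEFAULT_CONTRAST.items()})
    noise_sd: float = 10.0
    seed: int = 0
    case_id: str = "phantom"

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if len(self.grid_shape) != 3 or any(s < 8 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be three dims >= 8, got {self.grid_shape}")
        r_wt, r_tc, r_et = self.radii
        if not (r_wt > r_tc > r_et > 0):
            raise ValueError(f"radii must be strictly decreasing and positive, got {self.radii}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.tumor_center is None:
            self.tumor_center = tuple(s / 2.0 for s in self.grid_shape)
        brain_r = self.brain_radius_frac * min(self.grid_shape)
        center = np.asarray(self.grid_shape, dtype=float) / 2.0
        offset = np.linalg.norm(np.asarray(self.tumor_center, dtype=float) - center)
        if offset + max(self.radii) > brain_r:
            raise ValueError("tumor ellipsoid is not contained in the brain mask")
        missing = set(MODALITIES) - set(self.modality_contrast)
        if missing:
            raise ValueError(f"modality_contrast missing modalities: {sorted(missing)}")


@dataclasses.dataclass
class PhantomCase:
    stack: "ModalityStack"
    label: "LabelVolume"
    spec: PhantomSpec


def _ellipsoid(shape: tuple, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return r2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Render one phantom case from its spec.

    The whole-tumor ellipsoid is partitioned into an edema shell (2), a
    necrotic rim (1) and an enhancing core (4); the surrounding sphere is
    healthy brain (0, nonzero intensity) and everything outside the brain is
    zero in all four modalities.
    """
    from .preprocess import LabelVolume, ModalityStack  # local import avoids cycle

    rng = np.random.default_rng(spec.seed)
    shape = spec.grid_shape
    brain_r = spec.brain_radius_frac * min(shape)
    brain_center = tuple(s / 2.0 for s in shape)
    brain = _ellipsoid(shape, brain_center, (brain_r,) * 3)

    r_wt, r_tc, r_et = spec.radii
    wt = _ellipsoid(shape, spec.tumor_center, (r_wt,) * 3)
    tc = _ellipsoid(shape, spec.tumor_center, (r_tc,) * 3)
    et = _ellipsoid(shape, spec.tumor_center, (r_et,) * 3)

    label = np.zeros(shape, dtype=np.int16)
    label[wt] = 2          # edema shell
    label[tc] = 1          # necrotic rim
    label[et] = 4          # enhancing core

    compartment = {                      # boolean masks, mutually exclusive
        "brain": brain & ~wt,
        "edema": wt & ~tc,
        "necrotic": tc & ~et,
        "enhancing": et,
    }

    data = np.zeros((len(MODALITIES),) + shape, dtype=np.float32)
    for ci, modality in enumerate(MODALITIES):
        vol = np.zeros(shape, dtype=np.float32)
        for comp in COMPARTMENTS:
            vol[compartment[comp]] = spec.modality_contrast[modality][comp]
        if spec.noise_sd > 0:
            noise = rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)
            vol[brain] += noise[brain]
        np.clip(vol, 0.0, None, out=vol)
        data[ci] = vol

    affine = np.eye(4)
    stack = ModalityStack(data=data, affine=affine, case_id=spec.case_id)
    return PhantomCase(stack=stack, label=LabelVolume(data=label, affine=affine), spec=spec)


def generate_cohort(n: int, base_seed: int, grid_shape: tuple = (64, 64, 64),
                    noise_sd: float = 10.0) -> list[PhantomCase]:
    """Generate ``n`` cases with randomized tumor centers and radii.

    Per-case seeds are spawned from ``base_seed`` so the cohort is fully
    reproducible and individual cases can be re-rendered in isolation.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    grid_shape = tuple(int(s) for s in grid_shape)
    master = np.random.default_rng(base_seed)
    case_seeds = master.integers(0, 2**31 - 1, size=n)
    cases = []
    for i, seed in enumerate(case_seeds):
        rng = np.random.default_rng(int(seed))
        brain_r = 0.42 * min(grid_shape)
        r_wt = rng.uniform(0.28, 0.45) * brain_r
        r_tc = r_wt * rng.uniform(0.55, 0.75)
        r_et = r_tc * rng.uniform(0.4, 0.6)
        max_offset = brain_r - r_wt - 1.0
        center = np.asarray(grid_shape, dtype=float) / 2.0
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        center = center + direction * rng.uniform(0.0, max(max_offset, 0.0))
        spec = PhantomSpec(
            grid_shape=grid_shape,
            tumor_center=tuple(center),
            radii=(r_wt, r_tc, r_et),
            noise_sd=noise_sd,
            seed=int(seed),
            case_id=f"phantom{i:03d}",
        )
        cases.append(generate_phantom(spec))
    return cases


def write_case(case: PhantomCase, directory) -> list[Path]:
    """Write a case as five NIfTI files following the BraTS naming convention."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cid = case.spec.case_id
    paths = []
    for ci, modality in enumerate(MODALITIES):
        p = directory / f"{cid}_{modality}.nii.gz"
        nib.save(nib.Nifti1Image(case.stack.data[ci], case.stack.affine), p)
        paths.append(p)
    p = directory / f"{cid}_seg.nii.gz"
    nib.save(nib.Nifti1Image(case.label.data.astype(np.int16), case.label.affine), p)
    paths.append(p)
    return paths
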