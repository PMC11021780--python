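"""NIfTI case I/O, intensity standardization, cropping, augmentation, labels.

The canonical in-memory layout is channel-first: a stack is (4, D, H, W) with
modality order [FLAIR, T1, T1ce, T2], a label volume is (D, H, W) int with
values {0, 1, 2, 4}.  Coordinates are 0-based voxel indices in (depth, height,
width) order; the NIfTI affine is carried through untouched.

Z-score standardization follows the skull-stripped convention: per modality and
per case, statistics are taken over nonzero voxels only (the brain), with the
population (1/N) standard deviation, and background stays exactly zero.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import nibabel as nib
import numpy as np

log = logging.getLogger("cascadeseg")

MODALITIES = ("flair", "t1", "t1ce", "t2")
VALID_LABELS = frozenset({0, 1, 2, 4})
#: raw BraTS label -> contiguous class index
LABEL_TO_CLASS = {0: 0, 1: 1, 2: 2, 4: 3}
CLASS_TO_LABEL = np.array([0, 1, 2, 4], dtype=np.int16)
N_CLASSES = 4


@dataclasses.dataclass
class ModalityStack:
    """Four co-registered MRI contrasts of one case, channel-first."""

    data: np.ndarray          # (4, D, H, W) float32
    affine: np.ndarray        # 4x4
    case_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4 or self.data.shape[0] != len(MODALITIES):
            raise ValueError(f"stack must be (4, D, H, W), got {self.data.shape}")


@dataclasses.dataclass
class LabelVolume:
    data: np.ndarray          # (D, H, W) integer
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"label volume must be rank 3, got {self.data.shape}")
        _check_labels(self.data)


def _check_labels(arr: np.ndarray) -> None:
    present = set(np.unique(arr).tolist())
    bad = present - VALID_LABELS
    if bad:
        raise ValueError(f"label volume contains invalid values {sorted(bad)}; "
                         f"allowed: {sorted(VALID_LABELS)}")


@dataclasses.dataclass
class TrainingSample:
    """A normalized, cropped patch with its targets in two encodings."""

    inputs: np.ndarray          # (4, S, S, S) float32
    target_classes: np.ndarray  # (S, S, S) int, values {0,1,2,3}
    target_onehot: np.ndarray   # (4, S, S, S) float32, channels sum to 1


# ---- I/O -------------------------------------------------------------------

def load_case(directory, case_id: str) -> tuple[ModalityStack, LabelVolume | None]:
    """Load the four modality files (and the label file if present).

    Channels are stacked in the canonical [FLAIR, T1, T1ce, T2] order whatever
    the directory listing order.  Missing modality files raise an error naming
    the modality; a missing ``_seg`` file is an expected condition (validation
    cases) and yields ``None``.
    """
    directory = Path(directory)
    channels = []
    affine = None
    for modality in MODALITIES:
        path = _find(directory, case_id, modality)
        if path is None:
            raise FileNotFoundError(
                f"case '{case_id}' in {directory}: missing modality file '{modality}'")
        img = nib.load(path)
        channels.append(np.asarray(img.dataobj, dtype=np.float32))
        if affine is None:
            affine = img.affine
    stack = ModalityStack(data=np.stack(channels), affine=affine, case_id=case_id)
    seg_path = _find(directory, case_id, "seg")
    label = None
    if seg_path is not None:
        img = nib.load(seg_path)
        arr = np.asarray(img.dataobj)
        label = LabelVolume(data=np.rint(arr).astype(np.int16), affine=img.affine)
        if label.data.shape != stack.data.shape[1:]:
            raise ValueError(f"label shape {label.data.shape} does not match "
                             f"stack {stack.data.shape[1:]}")
    return stack, label


def _find(directory: Path, case_id: str, suffix: str) -> Path | None:
    for ext in (".nii.gz", ".nii"):
        p = directory / f"{case_id}_{suffix}{ext}"
        if p.exists():
            return p
    return None


def list_cases(directory) -> list[str]:
    """Case ids present in a directory, inferred from ``*_flair.nii*`` files."""
    directory = Path(directory)
    ids = set()
    for p in directory.glob("*_flair.nii*"):
        ids.add(p.name.split("_flair")[0])
    return sorted(ids)


def save_label(label: LabelVolume, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(label.data.astype(np.int16), label.affine), path)
    return path


# ---- standardization -------------------------------------------------------

def zscore_normalize(stack: ModalityStack, eps: float = 1e-8) -> ModalityStack:
    """Per-modality z-score over nonzero (brain) voxels; background stays 0.

    A channel whose nonzero region has spread below ``eps`` carries no
    intensity information; it is zeroed with a warning rather than divided by
    a vanishing deviation.
    """
    out = np.zeros_like(stack.data)
    for ci in range(stack.data.shape[0]):
        vol = stack.data[ci]
        mask = vol != 0
        if mask.sum() < 2:
            log.warning("modality %s of case '%s': fewer than 2 nonzero voxels; "
                        "channel zeroed", MODALITIES[ci], stack.case_id)
            continue
        vals = vol[mask]
        mu = vals.mean(dtype=np.float64)
        sd = vals.std(dtype=np.float64)   # population (1/N) deviation
        if sd < eps:
            log.warning("modality %s of case '%s': constant nonzero region; "
                        "channel zeroed", MODALITIES[ci], stack.case_id)
            continue
        out[ci][mask] = ((vals - mu) / sd).astype(np.float32)
    return ModalityStack(data=out, affine=stack.affine, case_id=stack.case_id)


# ---- label encodings -------------------------------------------------------

def remap_labels(label: LabelVolume | np.ndarray) -> np.ndarray:
    """Raw labels {0,1,2,4} -> contiguous class indices {0,1,2,3}."""
    arr = label.data if isinstance(label, LabelVolume) else np.asarray(label)
    _check_labels(arr)
    out = arr.astype(np.int16).copy()
    out[out == 4] = 3
    return out


def classes_to_labels(classes: np.ndarray) -> np.ndarray:
    """Inverse of :func:`remap_labels`."""
    classes = np.asarray(classes)
    if classes.min() < 0 or classes.max() >= N_CLASSES:
        raise ValueError("class indices must lie in {0,1,2,3}")
    return CLASS_TO_LABEL[classes]


def onehot(classes: np.ndarray, n_classes: int = N_CLASSES) -> np.ndarray:
    """Class-index volume -> (n_classes, ...) one-hot float tensor."""
    classes = np.asarray(classes)
    if classes.min() < 0 or classes.max() >= n_classes:
        raise ValueError(f"class values must be < {n_classes}")
    out = np.zeros((n_classes,) + classes.shape, dtype=np.float32)
    for c in range(n_classes):
        out[c] = classes == c
    return out


# ---- cropping & augmentation -----------------------------------------------

def _pad_to(arr: np.ndarray, size: int, spatial_axes: tuple) -> np.ndarray:
    pads = [(0, 0)] * arr.ndim
    for ax in spatial_axes:
        short = max(0, size - arr.shape[ax])
        pads[ax] = (short // 2, short - short // 2)
    if any(p != (0, 0) for p in pads):
        arr = np.pad(arr, pads)
    return arr


def random_crop(stack: ModalityStack, label: LabelVolume, size: int,
                rng: np.random.Generator, tumor_bias: float = 0.5) -> TrainingSample:
    """Crop a ``size``³ training patch, biased toward tumor tissue.

    With probability ``tumor_bias`` (when any tumor voxel exists) the window is
    centered on a uniformly drawn tumor voxel, countering the heavy class
    imbalance of whole volumes; otherwise the window corner is uniform.
    Volumes smaller than ``size`` are zero-padded symmetrically first, which
    cannot invent foreground (pad value 0 = healthy/background).
    """
    data = _pad_to(stack.data, size, (1, 2, 3))
    lab = _pad_to(np.asarray(label.data), size, (0, 1, 2))
    shape = lab.shape
    tumor_idx = np.argwhere(lab > 0)
    if tumor_idx.size and rng.random() < tumor_bias:
        center = tumor_idx[rng.integers(len(tumor_idx))]
        corner = [int(np.clip(c - size // 2, 0, s - size))
                  for c, s in zip(center, shape)]
    else:
        corner = [int(rng.integers(0, s - size + 1)) for s in shape]
    sl = tuple(slice(c, c + size) for c in corner)
    classes = remap_labels(lab[sl])
    return TrainingSample(
        inputs=np.ascontiguousarray(data[(slice(None),) + sl]),
        target_classes=classes,
        target_onehot=onehot(classes),
    )


def augment(sample: TrainingSample, rng: np.random.Generator,
            p_flip: float = 0.5, p_rot: float = 0.5,
            scale_range: tuple = (0.9, 1.1),
            shift_range: tuple = (-0.1, 0.1)) -> TrainingSample:
    """Label-safe geometric + intensity augmentation.

    Geometric part (axis flips, 90° rotations in the axial H-W plane) is
    applied identically to inputs and both target encodings; the affine
    intensity jitter touches the inputs only, so the label value set is
    preserved by construction.
    """
    inputs = sample.inputs
    classes = sample.target_classes
    hot = sample.target_onehot
    for ax in range(3):
        if rng.random() < p_flip:
            inputs = np.flip(inputs, axis=ax + 1)
            classes = np.flip(classes, axis=ax)
            hot = np.flip(hot, axis=ax + 1)
    if rng.random() < p_rot:
        k = int(rng.integers(1, 4))
        inputs = np.rot90(inputs, k=k, axes=(2, 3))
        classes = np.rot90(classes, k=k, axes=(1, 2))
        hot = np.rot90(hot, k=k, axes=(2, 3))
    scale = rng.uniform(*scale_range)
    shift = rng.uniform(*shift_range)
    inputs = inputs * np.float32(scale) + np.float32(shift)
    return TrainingSample(
        inputs=np.ascontiguousarray(inputs, dtype=np.float32),
        target_classes=np.ascontiguousarray(classes),
        target_onehot=np.ascontiguousarray(hot),
    )
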