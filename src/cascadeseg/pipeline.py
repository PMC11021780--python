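"""Training loop, sliding-window inference, checkpointing and evaluation runs.

Training follows the published recipe: Adam with first-moment decay 0.95,
decoupled weight decay 1e-5, initial learning rate 1e-3, batches of 3 random
128³ crops, 550 optimizer steps by default — every value configurable, and the
test suite exercises a desk-scale variant (32³ crops, base width 8).  The
dynamic-convolution softmax temperature is annealed linearly from 30 to 1 over
the first 30 % of steps to avoid early winner-take-all kernel collapse.

Inference tiles the volume with windows of the training crop size at 50 %
overlap, averages stage-2 softmax probabilities over overlaps, takes the
voxelwise argmax and maps class 3 back to raw label 4.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .autodiff import AdamW, Tensor
from .dynconv import DyConvConfig
from .ema import BasisSet, EmaConfig
from .losses import LossReport, LossWeights, composite_loss
from .metrics import CaseMetrics, aggregate, evaluate_case, metrics_table
from .network import CascadeNet
from .preprocess import (LabelVolume, ModalityStack, augment, classes_to_labels,
                         list_cases, load_case, random_crop, zscore_normalize)

log = logging.getLogger("cascadeseg")


@dataclasses.dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    weight_decay: float = 1e-5
    beta1: float = 0.95
    batch_size: int = 3
    iterations: int = 550
    crop_size: int = 128
    seed: int = 0
    base_width: int = 16
    norm_groups: int = 8
    dyconv_kernels: int = 4
    dyconv_reduction: int = 4
    ema_bases: int = 64
    ema_iterations: int = 3
    ema_momentum: float = 0.9
    tumor_bias: float = 0.5
    tau_start: float = 30.0
    tau_end: float = 1.0
    tau_anneal_frac: float = 0.3
    checkpoint_every: int = 0          # 0 = only at the end
    loss_weights: LossWeights = dataclasses.field(default_factory=LossWeights)

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.iterations < 1:
            raise ValueError("rates and counts must be positive")
        if self.crop_size % 16:
            raise ValueError("crop_size must be divisible by 16")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        lw = d.pop("loss_weights", None)
        cfg = cls(**d)
        if lw is not None:
            cfg.loss_weights = LossWeights(**lw) if isinstance(lw, dict) else lw
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def build_network(config: TrainConfig, rng: np.random.Generator) -> CascadeNet:
    dyconv = DyConvConfig(in_channels=1, out_channels=1,
                          n_kernels=config.dyconv_kernels,
                          reduction=config.dyconv_reduction,
                          temperature=config.tau_start)
    ema = EmaConfig(channels=config.base_width * 8, n_bases=config.ema_bases,
                    n_iterations=config.ema_iterations,
                    basis_momentum=config.ema_momentum)
    return CascadeNet(base_width=config.base_width, norm_groups=config.norm_groups,
                      dyconv=dyconv, ema=ema, rng=rng)


@dataclasses.dataclass
class CheckpointRecord:
    net: CascadeNet
    config: TrainConfig
    iteration: int
    loss_log: pd.DataFrame

    def save(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {f"param::{k}": p.data
                  for k, p in self.net.named_parameters().items()}
        if self.net.stage2.ema is not None:
            arrays["ema_bases"] = self.net.stage2.ema.global_bases.mu
        arrays["config_json"] = np.frombuffer(
            json.dumps(self.config.to_dict()).encode(), dtype=np.uint8)
        arrays["iteration"] = np.array(self.iteration)
        np.savez(path, **arrays)
        return path

    @classmethod
    def load(cls, path) -> "CheckpointRecord":
        with np.load(Path(path), allow_pickle=False) as npz:
            cfg = TrainConfig.from_dict(
                json.loads(bytes(npz["config_json"]).decode()))
            net = build_network(cfg, np.random.default_rng(cfg.seed))
            params = net.named_parameters()
            for key in npz.files:
                if key.startswith("param::"):
                    name = key[len("param::"):]
                    params[name].data = npz[key].astype(np.float32)
            if "ema_bases" in npz.files and net.stage2.ema is not None:
                net.stage2.ema.global_bases = BasisSet(mu=npz["ema_bases"])
            iteration = int(npz["iteration"])
        net.set_temperature(cfg.tau_end)
        return cls(net=net, config=cfg, iteration=iteration,
                   loss_log=pd.DataFrame())


def _temperature(step: int, config: TrainConfig) -> float:
    horizon = max(1, int(config.tau_anneal_frac * config.iterations))
    frac = min(1.0, step / horizon)
    return config.tau_start + frac * (config.tau_end - config.tau_start)


def load_training_cases(case_directory) -> list[tuple[ModalityStack, LabelVolume]]:
    """Load and z-score every labeled case in a directory."""
    case_ids = list_cases(case_directory)
    cases = []
    for cid in case_ids:
        stack, label = load_case(case_directory, cid)
        if label is None:
            continue
        cases.append((zscore_normalize(stack), label))
    if not cases:
        raise ValueError(f"no labeled cases found in {case_directory}")
    return cases


def train(config: TrainConfig, case_directory=None, *,
          cases: list[tuple[ModalityStack, LabelVolume]] | None = None,
          checkpoint_path=None, log_path=None) -> CheckpointRecord:
    """Train the cascade on the labeled cases of a directory (or in-memory).

    Per step: sample a batch of random tumor-biased crops, augment, run the
    cascade, average the composite loss over the batch, and take one AdamW
    step.  Fully seeded: data order, crops, augmentation and weight init all
    derive from ``config.seed``.
    """
    if cases is None:
        cases = load_training_cases(case_directory)
    rng = np.random.default_rng(config.seed)
    net = build_network(config, rng)
    opt = AdamW(net.parameters(), lr=config.learning_rate, beta1=config.beta1,
                weight_decay=config.weight_decay)
    rows = []
    log.info("training: %d cases, %d iterations, config %s",
             len(cases), config.iterations, config.config_hash())
    for step in range(1, config.iterations + 1):
        net.set_temperature(_temperature(step - 1, config))
        opt.zero_grad()
        total = None
        report: LossReport | None = None
        for _ in range(config.batch_size):
            stack, label = cases[rng.integers(len(cases))]
            sample = random_crop(stack, label, config.crop_size, rng,
                                 tumor_bias=config.tumor_bias)
            sample = augment(sample, rng)
            out = net.forward(Tensor(sample.inputs), training=True)
            loss, report = composite_loss(out.stage1_logits, out.stage2_logits,
                                          sample.target_onehot, config.loss_weights)
            total = loss if total is None else total + loss
        total = total * (1.0 / config.batch_size)
        if not np.isfinite(total.data):
            raise RuntimeError(
                f"non-finite loss at step {step}: {total.data!r} (last sample "
                f"report: {report})")
        total.backward()
        opt.step()
        rows.append({"step": step, "ce1": report.ce1, "ce2": report.ce2,
                     "dc2": report.dc2, "total": float(total.data),
                     "tau": _temperature(step - 1, config)})
        if step % 25 == 0 or step == 1:
            log.info("step %d/%d total=%.4f", step, config.iterations,
                     float(total.data))
        if (config.checkpoint_every and checkpoint_path
                and step % config.checkpoint_every == 0):
            CheckpointRecord(net, config, step, pd.DataFrame(rows)).save(checkpoint_path)
    loss_log = pd.DataFrame(rows)
    record = CheckpointRecord(net=net, config=config,
                              iteration=config.iterations, loss_log=loss_log)
    if checkpoint_path is not None:
        record.save(checkpoint_path)
    if log_path is not None:
        loss_log.to_csv(log_path, index=False)
    return record


# ---- inference -------------------------------------------------------------

def _window_starts(dim: int, window: int, stride: int) -> list[int]:
    starts = list(range(0, dim - window + 1, stride))
    if starts[-1] != dim - window:
        starts.append(dim - window)
    return starts


def predict(record: CheckpointRecord, stack: ModalityStack,
            normalize: bool = True) -> LabelVolume:
    """Sliding-window inference at 50 % overlap with probability averaging."""
    net, cfg = record.net, record.config
    net.set_temperature(cfg.tau_end)
    if normalize:
        stack = zscore_normalize(stack)
    data = stack.data
    orig_shape = data.shape[1:]
    window = cfg.crop_size
    pads = [(0, 0)]
    for s in orig_shape:
        short = max(0, window - s)
        pads.append((short // 2, short - short // 2))
    data = np.pad(data, pads)
    shape = data.shape[1:]
    stride = max(1, window // 2)
    prob_sum = np.zeros((4,) + shape, dtype=np.float32)
    count = np.zeros(shape, dtype=np.float32)
    for d0 in _window_starts(shape[0], window, stride):
        for h0 in _window_starts(shape[1], window, stride):
            for w0 in _window_starts(shape[2], window, stride):
                sl = (slice(None), slice(d0, d0 + window),
                      slice(h0, h0 + window), slice(w0, w0 + window))
                out = net.forward(Tensor(data[sl]), training=False)
                logits = out.stage2_logits.data
                logits = logits - logits.max(axis=0, keepdims=True)
                e = np.exp(logits)
                prob_sum[sl] += e / e.sum(axis=0, keepdims=True)
                count[sl[1:]] += 1.0
    probs = prob_sum / count[None]
    classes = probs.argmax(axis=0)
    unpad = tuple(slice(p[0], p[0] + s) for p, s in zip(pads[1:], orig_shape))
    labels = classes_to_labels(classes[unpad]).astype(np.int16)
    return LabelVolume(data=labels, affine=stack.affine)


def evaluate_directories(pred_dir, truth_dir, spacing=(1.0, 1.0, 1.0),
                         empty_penalty: float | None = None
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-case and aggregate Dice/HD95 tables for matching ``*_seg`` files."""
    import nibabel as nib

    pred_dir, truth_dir = Path(pred_dir), Path(truth_dir)
    case_ids = sorted(p.name.split("_seg")[0]
                      for p in truth_dir.glob("*_seg.nii*"))
    if not case_ids:
        raise ValueError(f"no *_seg files in {truth_dir}")
    results: list[CaseMetrics] = []
    for cid in case_ids:
        pred_path = _seg_path(pred_dir, cid)
        truth_path = _seg_path(truth_dir, cid)
        pred = np.rint(np.asarray(nib.load(pred_path).dataobj)).astype(np.int16)
        truth = np.rint(np.asarray(nib.load(truth_path).dataobj)).astype(np.int16)
        results.append(evaluate_case(pred, truth, case_id=cid, spacing=spacing,
                                     empty_penalty=empty_penalty))
    return metrics_table(results), aggregate(results)


def _seg_path(directory: Path, case_id: str) -> Path:
    for ext in (".nii.gz", ".nii"):
        p = directory / f"{case_id}_seg{ext}"
        if p.exists():
            return p
    raise FileNotFoundError(f"no segmentation for case '{case_id}' in {directory}")
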