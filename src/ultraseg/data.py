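"""BUSI-style dataset indexing, loading, and the resolution harness.

The on-disk layout pairs ``<class> (k).png`` images with one or more
``<class> (k)_mask*.png`` binary masks (multi-lesion images carry
``_mask_1``, ``_mask_2``, ... files which are combined by union).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import imageio.v3 as iio
from skimage.transform import resize

from .graph import ModelConfig
from .metrics import MetricReport
from .phantom import CLASS_LABELS, Sample
from .train import Hyperparams, evaluate, fit, split_dataset
from .network import build_network

__all__ = [
    "DatasetRecord",
    "DatasetIndex",
    "index_dataset",
    "load_sample",
    "load_all",
    "pad_to_multiple",
    "resolution_harness",
]

log = logging.getLogger("ultraseg.data")

MASK_THRESHOLD = 127  # 8-bit masks: values above are foreground

_STEM_RE = re.compile(r"^(?P<label>[A-Za-z]+) \((?P<k>\d+)\)$")


@dataclass(frozen=True)
class DatasetRecord:
    image_path: Path
    mask_paths: tuple[Path, ...]  # empty tuple = explicit empty-mask marker
    label: str


@dataclass(frozen=True)
class DatasetIndex:
    root: Path
    records: tuple[DatasetRecord, ...]

    def __len__(self) -> int:
        return len(self.records)

    def by_label(self, label: str) -> list[DatasetRecord]:
        return [r for r in self.records if r.label == label]


def index_dataset(root: str | Path) -> DatasetIndex:
    """Pair every image PNG with its mask PNGs.

    Images lacking a mask are indexed with an explicit empty-mask marker
    (and a warning); mask files with no matching image are reported too.
    Labels outside {normal, benign, malignant} raise.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    records = []
    claimed_masks: set[Path] = set()
    all_masks = sorted(root.glob("*_mask*.png"))
    images = sorted(p for p in root.glob("*.png") if "_mask" not in p.stem)
    for img in images:
        m = _STEM_RE.match(img.stem)
        label = m.group("label").lower() if m else img.stem.split()[0].lower()
        if label not in CLASS_LABELS:
            raise ValueError(f"unrecognised class label {label!r} for "
                             f"{img.name}; expected one of {CLASS_LABELS}")
        masks = tuple(sorted(root.glob(f"{img.stem}_mask*.png")))
        claimed_masks.update(masks)
        if not masks:
            warnings.warn(f"image {img.name} has no mask file; "
                          f"indexed with an empty mask")
        records.append(DatasetRecord(img, masks, label))
    orphans = [p.name for p in all_masks if p not in claimed_masks]
    if orphans:
        warnings.warn(f"unmatched mask files: {', '.join(orphans)}")
    return DatasetIndex(root=root, records=tuple(records))


def _read_gray(path: Path) -> np.ndarray:
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise IOError(f"cannot read PNG {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:  # luminance conversion for any RGB(A) input
        arr = (0.2126 * arr[..., 0] + 0.7152 * arr[..., 1]
               + 0.0722 * arr[..., 2])
    return arr.astype(np.float64)


def load_sample(record: DatasetRecord, target_size: int | tuple[int, int],
                mask_policy: str = "union") -> Sample:
    """Load one record: image scaled to [0,1] and resized bilinearly, masks
    thresholded at >127, combined by union, resized nearest-neighbour."""
    if mask_policy != "union":
        raise ValueError(f"unknown mask policy {mask_policy!r}")
    if isinstance(target_size, int):
        target_size = (target_size, target_size)
    img = _read_gray(record.image_path) / 255.0
    if img.shape != target_size:
        img = resize(img, target_size, order=1, preserve_range=True,
                     anti_aliasing=img.shape[0] > target_size[0])
    img = np.clip(img, 0.0, 1.0)
    if record.mask_paths:
        mask = np.zeros_like(_read_gray(record.mask_paths[0]), dtype=bool)
        for mp in record.mask_paths:
            mask |= _read_gray(mp) > MASK_THRESHOLD
    else:
        mask = np.zeros(img.shape, dtype=bool)
    mask = mask.astype(np.uint8)
    if mask.shape != target_size:
        mask = (resize(mask.astype(np.float64), target_size, order=0,
                       preserve_range=True, anti_aliasing=False)
                > 0.5).astype(np.uint8)
    return Sample(image=img, mask=mask, label=record.label, seed=0)


def load_all(index: DatasetIndex, target_size: int | tuple[int, int]
             ) -> list[Sample]:
    return [load_sample(r, target_size) for r in index.records]


def pad_to_multiple(size: int, multiple: int = 16) -> int:
    return int(-(-size // multiple) * multiple)


def _pad_reflect(arr: np.ndarray, target: int) -> np.ndarray:
    ph, pw = target - arr.shape[0], target - arr.shape[1]
    if ph == 0 and pw == 0:
        return arr
    return np.pad(arr, ((0, ph), (0, pw)), mode="reflect")


def resolution_harness(samples: list[Sample], sizes: list[int],
                       hp: Hyperparams, base_config: ModelConfig,
                       train_fraction: float = 0.85
                       ) -> dict[int, MetricReport]:
    """Train and evaluate one model per image size on identically split data.

    Sizes that are not multiples of 16 (e.g. 500) are padded reflectively
    up to the next multiple (500 -> 512) for the network; predictions are
    cropped back before scoring, so the metrics always refer to the
    requested size.  Returns one metric report per size (F1, Dice,
    precision, recall among them).
    """
    train_idx, eval_idx = split_dataset(len(samples), train_fraction,
                                        hp.seed)
    results: dict[int, MetricReport] = {}
    for size in sizes:
        padded = pad_to_multiple(size)
        resized = []
        for s in samples:
            img = resize(s.image, (size, size), order=1, preserve_range=True,
                         anti_aliasing=s.image.shape[0] > size)
            msk = (resize(s.mask.astype(np.float64), (size, size), order=0,
                          preserve_range=True, anti_aliasing=False)
                   > 0.5).astype(np.uint8)
            resized.append(Sample(image=_pad_reflect(img, padded),
                                  mask=_pad_reflect(msk, padded),
                                  label=s.label, seed=s.seed))
        cfg = base_config.with_size(padded, padded)
        net = build_network(cfg)
        train_set = [resized[i] for i in train_idx]
        rng = np.random.default_rng(hp.seed)
        perm = rng.permutation(len(train_set))
        n_val = max(1, int(round(hp.val_fraction * len(train_set))))
        val_set = [train_set[i] for i in perm[:n_val]]
        fit_set = [train_set[i] for i in perm[n_val:]]
        net, _ = fit(net, fit_set, val_set, hp)
        # score on the crop back to the requested size
        eval_set = [resized[i] for i in eval_idx]
        cropped = [_crop_sample(s, size) for s in eval_set]
        results[size] = _evaluate_cropped(net, eval_set, cropped, size,
                                          hp.batch_size)
        log.info("size %d: dice=%.4f f1=%.4f", size, results[size].dice,
                 results[size].f1)
    return results


def _crop_sample(s: Sample, size: int) -> Sample:
    return Sample(image=s.image[:size, :size], mask=s.mask[:size, :size],
                  label=s.label, seed=s.seed)


def _evaluate_cropped(net, padded_samples: list[Sample],
                      cropped_samples: list[Sample], size: int,
                      batch: int) -> MetricReport:
    from .metrics import basic_metrics, confusion, roc_auc
    from .train import BINARIZE_THRESHOLD, _predict_probs

    probs = _predict_probs(net, padded_samples, batch)[:, :size, :size]
    truth = np.stack([s.mask for s in cropped_samples]).astype(np.uint8)
    pred = (probs >= BINARIZE_THRESHOLD).astype(np.uint8)
    report = basic_metrics(confusion(pred, truth))
    try:
        report.auc = roc_auc(probs, truth)
    except ValueError:
        pass
    return report
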