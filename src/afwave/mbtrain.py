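"""Balanced partitioning, branch-indexed loss, training, and prediction.

Class imbalance is handled structurally: the majority (normal) class D- is
shuffled and split into N_b near-equal subsets, each paired with the entire
minority (AF) class D+ to form N_b roughly balanced sub-datasets.  One output
branch trains on each sub-dataset, so every AF sample contributes to all
branches while every normal sample contributes to exactly one.  The loss is
the branch-indexed binary cross-entropy

    L = - sum_j sum_i 1[j in D_i] * ( y_j log P_i(X_j) + (1-y_j) log(1-P_i(X_j)) )

minimized with Adam; inference averages the N_b branch probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, InputError, TrainingError
from .model import MBResNet

__all__ = [
    "LabeledDataset",
    "BalancedPartition",
    "BranchPrediction",
    "make_partition",
    "mb_loss",
    "train",
    "predict",
    "subject_disjoint_split",
]

_EPS = 1e-7  # log clamp keeping the cross-entropy finite


@dataclass
class LabeledDataset:
    """Scalogram images with binary labels and subject ids.

    ``images`` is (N, 1, H, W) (or None for label-only bookkeeping such as
    partition sizing); labels are 1 = AF, 0 = normal.
    """

    labels: np.ndarray
    images: np.ndarray | None = None
    subjects: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise InputError("labels must be a non-empty 1-D array")
        if not np.all(np.isin(self.labels, (0, 1))):
            raise InputError("labels must be binary {0, 1}")
        if self.images is not None:
            self.images = np.asarray(self.images, dtype=np.float32)
            if self.images.shape[0] != self.labels.size:
                raise InputError("images and labels disagree in length")
        if self.subjects is not None:
            self.subjects = np.asarray(self.subjects)
            if self.subjects.size != self.labels.size:
                raise InputError("subjects and labels disagree in length")

    def __len__(self) -> int:
        return self.labels.size

    @property
    def d_minus(self) -> np.ndarray:
        """Indices of the majority normal class (y = 0)."""
        return np.flatnonzero(self.labels == 0)

    @property
    def d_plus(self) -> np.ndarray:
        """Indices of the minority AF class (y = 1)."""
        return np.flatnonzero(self.labels == 1)

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            labels=self.labels[idx],
            images=None if self.images is None else self.images[idx],
            subjects=None if self.subjects is None else self.subjects[idx],
        )


@dataclass
class BalancedPartition:
    """Disjoint shuffled subsets of D- covering it; subset i plus the whole
    D+ is the balanced sub-dataset of branch i."""

    subsets: list = field(default_factory=list)
    n_branches: int = 1

    def branch_of(self, n_total: int) -> np.ndarray:
        """Per-sample branch index for normals, -1 for samples not in any
        subset (i.e. AF samples, which belong to every branch)."""
        out = np.full(n_total, -1, dtype=int)
        for i, sub in enumerate(self.subsets):
            out[sub] = i
        return out


def make_partition(
    data: LabeledDataset,
    n_branches: int | None = None,
    seed: int = 0,
) -> BalancedPartition:
    """Shuffle D- and split it into N_b near-equal subsets.

    When ``n_branches`` is omitted it defaults to the rounded imbalance ratio
    max(1, round(|D-| / |D+|)), which makes each subset roughly the size of
    D+ — e.g. 5050 normal / 738 AF gives the ~7:1 ratio and N_b = 7.
    """
    d_minus, d_plus = data.d_minus, data.d_plus
    if d_minus.size == 0 or d_plus.size == 0:
        raise InputError("both classes must be non-empty to build a partition")
    if n_branches is None:
        n_branches = max(1, round(d_minus.size / d_plus.size))
    if n_branches < 1:
        raise ConfigError("n_branches must be >= 1")
    if n_branches > d_minus.size:
        raise ConfigError("more branches than majority samples")
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(d_minus)
    subsets = [np.sort(s) for s in np.array_split(shuffled, n_branches)]
    return BalancedPartition(subsets=subsets, n_branches=n_branches)


def mb_loss(
    predictions: np.ndarray,
    labels: np.ndarray,
    branch_of: np.ndarray,
    eps: float = _EPS,
) -> float:
    """Branch-indexed binary cross-entropy (sum reduction, as defined).

    ``predictions`` is (N, N_b) per-branch probabilities; ``branch_of[j]`` is
    the branch owning normal sample j, or -1 for AF samples, which enter
    every branch term.  Probabilities are clamped to [eps, 1 - eps].
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.ndim != 2 or p.shape[0] != y.size:
        raise InputError("predictions must be (N, n_branches)")
    if p.min() < 0 or p.max() > 1:
        raise InputError("probabilities must lie in [0, 1]")
    pc = np.clip(p, eps, 1 - eps)
    term = y[:, None] * np.log(pc) + (1 - y[:, None]) * np.log(1 - pc)
    mask = _branch_mask(branch_of, p.shape[1])
    return float(-(term * mask).sum())


def _branch_mask(branch_of: np.ndarray, n_branches: int) -> np.ndarray:
    """(N, N_b) indicator 1[j in D_i]."""
    branch_of = np.asarray(branch_of, dtype=int)
    mask = np.zeros((branch_of.size, n_branches))
    af = branch_of < 0
    mask[af, :] = 1.0
    rows = np.flatnonzero(~af)
    mask[rows, branch_of[rows]] = 1.0
    return mask


@dataclass
class BranchPrediction:
    """Per-branch AF probabilities and their arithmetic mean."""

    per_branch: np.ndarray

    def __post_init__(self) -> None:
        self.per_branch = np.atleast_2d(np.asarray(self.per_branch, dtype=float))
        if self.per_branch.min() < 0 or self.per_branch.max() > 1:
            raise InputError("branch probabilities must lie in [0, 1]")

    @property
    def mean(self) -> np.ndarray:
        return self.per_branch.mean(axis=1)

    @property
    def label(self) -> np.ndarray:
        """Hard classification at the 0.5 operating threshold."""
        return (self.mean >= 0.5).astype(int)


def predict(net: MBResNet, images: np.ndarray, batch_size: int = 64) -> BranchPrediction:
    """Per-branch probabilities and averaged prediction for a batch of
    scalogram images (inference mode: running batch-norm statistics)."""
    images = np.asarray(images, dtype=np.float32)
    if images.ndim == 3:
        images = images[:, None]
    chunks = [
        net.forward(images[i : i + batch_size], train=False)
        for i in range(0, images.shape[0], batch_size)
    ]
    return BranchPrediction(per_branch=np.concatenate(chunks, axis=0))


def train(
    data: LabeledDataset,
    net: MBResNet,
    lr: float = 1e-3,
    epochs: int = 50,
    batch_size: int = 32,
    seed: int = 0,
    n_branches: int | None = None,
    partition: BalancedPartition | None = None,
) -> dict:
    """Train the network on balanced sub-datasets with Adam.

    The partition of D- is built once per run (seeded) unless one is passed
    in.  Mini-batches are drawn from the union dataset; each sample's loss is
    routed to its branch(es) by the indicator of the branch-indexed
    cross-entropy.  Returns a history dict with per-epoch training loss
    (mean over samples) and the partition used.
    """
    if data.images is None:
        raise InputError("training requires images")
    if lr <= 0:
        raise ConfigError("lr must be positive")
    if partition is None:
        partition = make_partition(data, n_branches=n_branches, seed=seed)
    if partition.n_branches != net.n_branches:
        raise ConfigError(
            f"partition has {partition.n_branches} branches, network has {net.n_branches}"
        )

    from .nn import Adam  # local import keeps module load light

    branch_of = partition.branch_of(len(data))
    mask_all = _branch_mask(branch_of, net.n_branches).astype(np.float32)
    y = data.labels.astype(np.float32)

    opt = Adam(net.params(), lr=lr)
    rng = np.random.default_rng(seed + 1)
    history = {"loss": [], "partition": partition}
    n = len(data)
    for _epoch in range(epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb = data.images[idx]
            yb = y[idx]
            mb = mask_all[idx]

            opt.zero_grad()
            probs = net.forward(xb, train=True)
            pc = np.clip(probs, _EPS, 1 - _EPS)
            loss_terms = -(yb[:, None] * np.log(pc) + (1 - yb[:, None]) * np.log(1 - pc))
            loss = float((loss_terms * mb).sum())
            total += loss
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {_epoch}")
            # d(sum BCE)/d(logit) = (p - y) on included (sample, branch) terms.
            grad_logits = (probs - yb[:, None]) * mb
            net.backward_from_logits(grad_logits)
            opt.step()
        history["loss"].append(total / n)
    return history


def subject_disjoint_split(
    data: LabeledDataset,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Inter-patient 80/20 split: no subject appears on both sides.

    Subjects are shuffled within each class so both classes are represented
    in the test set at roughly the requested fraction.
    """
    if data.subjects is None:
        raise InputError("split requires subject ids")
    if not 0 < test_fraction < 1:
        raise ConfigError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    test_subjects: list = []
    for cls in (0, 1):
        subs = np.unique(data.subjects[data.labels == cls])
        subs = rng.permutation(subs)
        k = max(1, int(round(test_fraction * subs.size)))
        test_subjects += list(subs[:k])
    is_test = np.isin(data.subjects, test_subjects)
    return np.flatnonzero(~is_test), np.flatnonzero(is_test)
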