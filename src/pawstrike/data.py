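"""Stratified splitting, augmentation and batching of labeled clips.

The labeled datasets are heavily imbalanced (roughly two thirds of all
seconds are 0 Hz), so train/test splitting is stratified by frequency
class.  Training data may be expanded eight-fold by flipping (identity,
horizontal, vertical, both) with and without additive Gaussian pixel
noise; flips and noise leave the strike count — and hence the label —
unchanged.  Augmentation is applied to the training side only: test
clips stay raw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import FrameStack

__all__ = [
    "SplitIndices",
    "stratified_split",
    "augment_clip",
    "augment_frames",
    "make_batches",
    "DEFAULT_NOISE_SIGMA",
]

# The published augmentation recipe leaves the noise magnitude unstated;
# 0.02 on [0,1] intensities is visible but label-preserving.
DEFAULT_NOISE_SIGMA = 0.02


@dataclass(frozen=True)
class SplitIndices:
    """Disjoint train/test index lists covering 0..n-1."""

    train: tuple[int, ...]
    test: tuple[int, ...]

    def __post_init__(self) -> None:
        tr, te = set(self.train), set(self.test)
        if tr & te:
            raise ValueError("train and test indices overlap")
        n = len(self.train) + len(self.test)
        if tr | te != set(range(n)):
            raise ValueError("train/test do not partition 0..n-1")


def stratified_split(
    labels: Sequence[int], test_fraction: float, seed: int
) -> SplitIndices:
    """Per-class random split into train/test at ``test_fraction``.

    Within each class, members are assigned to the test side uniformly at
    random.  Per-class test counts use largest-remainder rounding so the
    overall test size equals ``round(n * test_fraction)`` exactly (e.g.
    4800 labels at 0.1 give 4320 train / 480 test, and 1000 give
    900/100).  A class whose test allotment would empty its training side
    keeps that member in train, with a warning.
    """
    if not 0 < test_fraction < 1:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    labels = np.asarray(labels)
    n = len(labels)
    if n == 0:
        raise ValueError("cannot split an empty label list")
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(labels, return_counts=True)
    total_test = round(n * test_fraction)

    exact = counts * test_fraction
    alloc = np.floor(exact).astype(int)
    remainders = exact - alloc
    short = total_test - alloc.sum()
    # hand out the leftover slots by largest remainder (ties: lower class)
    order = np.lexsort((classes, -remainders))
    for idx in order[:short]:
        alloc[idx] += 1
    # never empty a class's training side
    for i, cls in enumerate(classes):
        if alloc[i] >= counts[i] and counts[i] >= 1:
            warnings.warn(
                f"class {cls} has only {counts[i]} member(s); keeping one in train",
                stacklevel=2,
            )
            freed = alloc[i] - (counts[i] - 1)
            alloc[i] = counts[i] - 1
            # reassign freed slots to classes with room, by largest remainder
            for j in order:
                while freed > 0 and alloc[j] < counts[j] - 1:
                    alloc[j] += 1
                    freed -= 1

    test_idx: list[int] = []
    for i, cls in enumerate(classes):
        members = np.flatnonzero(labels == cls)
        chosen = rng.choice(members, size=alloc[i], replace=False)
        test_idx.extend(int(x) for x in chosen)
    test_set = set(test_idx)
    train_idx = [i for i in range(n) if i not in test_set]
    return SplitIndices(train=tuple(train_idx), test=tuple(sorted(test_idx)))


def augment_frames(
    pixels: np.ndarray, noise_sigma: float, seed: int
) -> list[np.ndarray]:
    """The eight augmentation variants of a (30, H, W) clip array.

    Order: [original, horizontal flip, vertical flip, both flips], then
    the same four with i.i.d. Gaussian pixel noise added and intensities
    clipped back to [0, 1].  Flips are applied identically to all 30
    frames.  The first variant is bit-identical to the input.
    """
    if noise_sigma <= 0:
        raise ValueError(f"noise_sigma must be > 0, got {noise_sigma}")
    pixels = np.asarray(pixels)
    rng = np.random.default_rng(seed)
    flips = [
        pixels,
        pixels[:, :, ::-1],  # horizontal: mirror the width axis
        pixels[:, ::-1, :],  # vertical: mirror the height axis
        pixels[:, ::-1, ::-1],
    ]
    noisy = [
        np.clip(f + rng.normal(0.0, noise_sigma, size=f.shape), 0.0, 1.0).astype(
            pixels.dtype
        )
        for f in flips
    ]
    return [f.copy() for f in flips] + noisy


def augment_clip(
    stack: FrameStack, noise_sigma: float = DEFAULT_NOISE_SIGMA, seed: int = 0
) -> list[FrameStack]:
    """Eight augmentation variants of a clip as FrameStacks."""
    variants = augment_frames(stack.pixels, noise_sigma, seed)
    return [
        FrameStack(v, fps=stack.fps, origin=stack.origin) for v in variants
    ]


def make_batches(
    indices: Sequence[int], batch_size: int, seed: int
) -> list[np.ndarray]:
    """Seeded shuffle of ``indices`` partitioned into mini-batches.

    The final short batch is retained, so every index appears exactly
    once.  Different seeds (e.g. one derived per epoch) give different
    orderings over the same index multiset.
    """
    if batch_size < 1:
        raise ValueError(f"batch_size must be >= 1, got {batch_size}")
    indices = np.asarray(indices)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(indices)
    return [perm[i : i + batch_size] for i in range(0, len(perm), batch_size)]
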