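"""Split protocol, balanced resampling, and catalog statistics.

The split protocol is stratified per class: each class is partitioned into a
training and a test part at a requested training fraction, with the train
count rounded to the nearest integer and clamped so both parts stay
non-empty.  Test spectra are never seen by training.

Balanced resampling draws a fixed, equal number of training indices per
class *with replacement*, so minority manufacturers contribute as many
spectra to each training pass as majority ones — the fairness device that
counteracts the long-tail class imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import ClassCatalog, SpectralDataset

__all__ = [
    "SplitPlan",
    "per_class_train_count",
    "stratified_split",
    "balanced_resample",
    "DatasetStats",
    "dataset_stats",
]


@dataclass(frozen=True)
class SplitPlan:
    """Per-class train/test index partition of a dataset."""

    train_fraction: float
    train_indices: dict[int, np.ndarray]   # class_id -> row indices
    test_indices: dict[int, np.ndarray]
    rng_seed: int

    @property
    def class_ids(self) -> list[int]:
        return sorted(self.train_indices)

    def all_train(self) -> np.ndarray:
        """All training rows, ordered by class then draw order."""
        return np.concatenate([self.train_indices[c] for c in self.class_ids])

    def all_test(self) -> np.ndarray:
        return np.concatenate([self.test_indices[c] for c in self.class_ids])


def per_class_train_count(n: int, train_fraction: float) -> int:
    """Training count for a class of size `n`: round(f*n) clamped to [1, n-1].

    Rounding to nearest (half away from zero) reproduces the printed worked
    examples of the benchmark protocol: a 21-sample class keeps 6 training
    spectra at 30% and 4 at 20%, and a 94-sample class at 90% keeps 85,
    leaving nine for testing.
    """
    if n < 2:
        raise ValueError(f"a class needs at least 2 samples to split, got {n}")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    count = int(np.floor(train_fraction * n + 0.5))
    return max(1, min(n - 1, count))


def stratified_split(
    dataset: SpectralDataset,
    train_fraction: float,
    rng_seed: int,
) -> SplitPlan:
    """Partition every class into train/test parts at `train_fraction`.

    Selection is uniform without replacement under the seed; re-running with
    the same seed reproduces identical index sets.
    """
    rng = np.random.default_rng(rng_seed)
    train: dict[int, np.ndarray] = {}
    test: dict[int, np.ndarray] = {}
    for class_id in np.unique(dataset.class_ids):
        rows = dataset.class_indices(int(class_id))
        if len(rows) < 2:
            raise ValueError(
                f"class {class_id} has {len(rows)} sample(s); at least 2 are needed to split"
            )
        n_train = per_class_train_count(len(rows), train_fraction)
        perm = rng.permutation(len(rows))
        train[int(class_id)] = np.sort(rows[perm[:n_train]])
        test[int(class_id)] = np.sort(rows[perm[n_train:]])
    return SplitPlan(train_fraction, train, test, rng_seed)


def balanced_resample(
    split: SplitPlan,
    dataset: SpectralDataset,
    n_per_class: int,
    rng_seed: int,
) -> np.ndarray:
    """Draw exactly `n_per_class` training rows per class, with replacement.

    Returns a flat index array of length ``k * n_per_class`` (class blocks in
    class-id order).  Every class contributes equally regardless of its pool
    size, so each draw may repeat rows of small classes.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(rng_seed)
    out = []
    for class_id in split.class_ids:
        pool = split.train_indices[class_id]
        if len(pool) == 0:
            raise ValueError(f"class {class_id} has an empty training pool")
        out.append(rng.choice(pool, size=n_per_class, replace=True))
    return np.concatenate(out)


@dataclass(frozen=True)
class DatasetStats:
    """Summary statistics of a class catalog."""

    total: int
    mean_floor: int          # floored mean class size
    max_count: int
    min_count: int
    top_k: int
    top_k_mass_pct: float    # % of all samples held by the top_k largest classes
    remaining_mass_pct: float
    train_fraction: float | None = None
    small_class_threshold: int | None = None
    n_small_classes: int | None = None   # classes with train count <= threshold


def dataset_stats(
    catalog: ClassCatalog,
    top_k: int = 8,
    train_fraction: float | None = None,
    small_class_threshold: int = 10,
) -> DatasetStats:
    """Imbalance statistics of a catalog, optionally under a split fraction.

    `top_k_mass_pct` is the share of all samples held by the `top_k` largest
    classes.  With `train_fraction` given, `n_small_classes` counts classes
    whose training part would hold at most `small_class_threshold` spectra.
    """
    if not 1 <= top_k <= catalog.k:
        raise ValueError(f"top_k must be in [1, {catalog.k}], got {top_k}")
    counts = catalog.counts
    total = int(counts.sum())
    top = np.sort(counts)[::-1][:top_k]
    top_pct = 100.0 * top.sum() / total
    n_small = None
    threshold = None
    if train_fraction is not None:
        threshold = small_class_threshold
        n_small = int(
            sum(
                per_class_train_count(int(n), train_fraction) <= small_class_threshold
                for n in counts
            )
        )
    return DatasetStats(
        total=total,
        mean_floor=int(counts.mean() // 1),
        max_count=int(counts.max()),
        min_count=int(counts.min()),
        top_k=top_k,
        top_k_mass_pct=float(top_pct),
        remaining_mass_pct=float(100.0 - top_pct),
        train_fraction=train_fraction,
        small_class_threshold=threshold,
        n_small_classes=n_small,
    )
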