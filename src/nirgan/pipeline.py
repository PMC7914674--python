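"""High-level pipeline: simulate -> split -> fit -> predict.

Thin orchestration over the library modules, shared by the command-line
interface, the examples, and the benchmark harness.
"""

from __future__ import annotations

import numpy as np

from . import bigan, synth
from .bigan import BiGANModel, LossTrace, build_model
from .config import RunConfig, substream_seed
from .datasets import ClassCatalog, SpectralDataset, WavenumberGrid, reference_catalog
from .dataops import SplitPlan
from .inference import predict_batch

__all__ = ["simulate", "fit", "BiGANClassifier"]


def simulate(config: RunConfig, catalog: ClassCatalog | None = None) -> SpectralDataset:
    """Generate a synthetic benchmark collection under the configuration.

    Uses the bundled 29-manufacturer catalog unless another is given; the
    simulate substream of the master seed drives archetypes, manufacturer
    profiles, and noise independently of the later stages.
    """
    catalog = catalog or reference_catalog()
    grid = WavenumberGrid(config.grid_start, config.grid_end, config.n_channels)
    seed = substream_seed(config.seed, "simulate")
    archetypes = synth.sample_archetypes(catalog.n_drugs, grid, rng_seed=seed)
    profiles = synth.derive_manufacturer_profiles(
        archetypes, catalog, config.manufacturer_effect, rng_seed=seed + 1)
    return synth.generate_dataset(profiles, catalog, config.noise_sd, grid,
                                  rng_seed=seed + 2, scatter_sd=config.scatter_sd)


def fit(dataset: SpectralDataset, split: SplitPlan, config: RunConfig,
        ) -> tuple[BiGANModel, list[float], LossTrace]:
    """Build, pre-train and adversarially train a model on the split.

    Returns (model, classifier pre-training trace, adversarial loss trace).
    """
    catalog = dataset.catalog or _catalog_from_labels(dataset)
    tc = config.train_config()
    if tc.n_channels != dataset.n_channels:
        tc.n_channels = dataset.n_channels
    model = build_model(catalog, tc)
    pre_trace = bigan.pretrain_classifier(model, dataset, split)
    trace = bigan.train(model, dataset, split)
    return model, pre_trace, trace


def _catalog_from_labels(dataset: SpectralDataset) -> ClassCatalog:
    ids, counts = np.unique(dataset.class_ids, return_counts=True)
    drug_of = {int(c): int(d) for c, d in zip(dataset.class_ids, dataset.drug_ids)}
    return ClassCatalog(tuple(
        (int(c), drug_of[int(c)], int(n)) for c, n in zip(ids, counts)))


class BiGANClassifier:
    """fit/predict wrapper so the model can enter the benchmark harness.

    `fit` receives a training matrix and labels (the harness has already
    split), builds an internal single-partition dataset, and runs classifier
    pre-training plus adversarial training; `predict` runs majority-vote
    inference.
    """

    def __init__(self, config: RunConfig, grid: WavenumberGrid,
                 drug_of: dict[int, int] | None = None):
        self.config = config
        self.grid = grid
        self.drug_of = drug_of or {}
        self.model: BiGANModel | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BiGANClassifier":
        y = np.asarray(y, dtype=int)
        drug_ids = np.array([self.drug_of.get(int(c), 1) for c in y])
        ds = SpectralDataset(X=X, class_ids=y, drug_ids=drug_ids, grid=self.grid)
        # the harness already held out the test part: train on everything given
        train_idx = {int(c): ds.class_indices(int(c)) for c in np.unique(y)}
        empty = {int(c): np.array([], dtype=int) for c in np.unique(y)}
        split = SplitPlan(1.0 - 1e-9, train_idx, empty, rng_seed=self.config.seed)
        self.model, _, _ = fit(ds, split, self.config)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("fit must be called first")
        ds = SpectralDataset(X=X, class_ids=np.ones(len(X), dtype=int),
                             drug_ids=np.ones(len(X), dtype=int), grid=self.grid)
        preds, _ = predict_batch(self.model, ds, repeats=self.config.repeats,
                                 rng_seed=substream_seed(self.config.seed, "predict"))
        return preds
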