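"""Majority-vote generative inference.

The deployed predictor chains the three trained networks: a query spectrum x
is encoded, a conditioned prior P(E(x)) is formed around its encoding, and a
latent code is sampled, decoded by the generator and classified.  Because
the latent sample is stochastic, each repetition classifies a *different*
synthetic spectrum of the same template; repeating a fixed number of times
and taking the modal class makes the prediction robust to occasional
sampling anomalies.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .bigan import BiGANModel, encode, softmax, update_prior
from .datasets import SpectralDataset

__all__ = ["VoteRecord", "predict_one", "predict_batch", "DEFAULT_REPEATS"]

DEFAULT_REPEATS = 15   # odd, to reduce ties


@dataclass(frozen=True)
class VoteRecord:
    """Vote histogram of one majority-vote prediction."""

    counts: np.ndarray        # (k,) votes per class, index 0 = class 1
    winner: int               # 1-based class id
    win_fraction: float

    @property
    def repeats(self) -> int:
        return int(self.counts.sum())


def _tally(class_votes: np.ndarray, k: int) -> VoteRecord:
    counts = np.bincount(class_votes - 1, minlength=k)
    winner = int(np.argmax(counts)) + 1   # argmax takes the lowest id on ties
    return VoteRecord(counts=counts, winner=winner,
                      win_fraction=float(counts[winner - 1] / counts.sum()))


def _inference_sigma(model: BiGANModel, mu: np.ndarray,
                     sigma_override: float | np.ndarray | None) -> np.ndarray:
    if sigma_override is not None:
        return np.broadcast_to(np.asarray(sigma_override, dtype=float), mu.shape).copy()
    if model.class_priors:
        # the query's class is unknown at inference; use the mean trained
        # within-class sigma as the local variance around its encoding
        return np.mean([p.sigma for p in model.class_priors.values()], axis=0)
    # frozen copy of the trained global prior, recentered on the query
    return update_prior(model.prior, mu).sigma


def predict_one(model: BiGANModel, x: np.ndarray, repeats: int = DEFAULT_REPEATS,
                rng_seed: int = 0,
                sigma_override: float | np.ndarray | None = None) -> VoteRecord:
    """Majority-vote class prediction for one spectrum.

    Each repeat samples z ~ N(E(x), sigma^2), generates G(z) and classifies
    it; the winner is the modal class, ties broken toward the lowest class
    id.  `sigma_override` replaces the trained prior scale (0 gives
    deterministic, unanimous votes).
    """
    if not model.trained:
        raise RuntimeError("model must be trained before prediction")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rng = np.random.default_rng(rng_seed)
    mu = encode(model, x)
    sigma = _inference_sigma(model, mu, sigma_override)
    z = mu[None, :] + sigma[None, :] * rng.standard_normal((repeats, mu.shape[0]))
    x_syn = model.G.forward(z, train=False)          # scaled space
    probs = softmax(model.C.forward(x_syn, train=False))
    votes = np.argmax(probs, axis=1) + 1
    return _tally(votes, model.k)


def _row_seed(rng_seed: int, sample_id: str) -> list[int]:
    """Stable per-row seed material: permuting rows permutes outputs."""
    return [int(rng_seed) & 0x7FFFFFFF, zlib.crc32(sample_id.encode())]


def predict_batch(model: BiGANModel, dataset: SpectralDataset,
                  repeats: int = DEFAULT_REPEATS, rng_seed: int = 0,
                  sigma_override: float | np.ndarray | None = None,
                  ) -> tuple[np.ndarray, list[VoteRecord]]:
    """Row-wise majority-vote prediction with independent per-row streams.

    Each row's sampling stream is derived from (rng_seed, sample_id), so the
    result for a given spectrum does not depend on its position in the
    batch.  Returns (predicted class ids, vote records).
    """
    records: list[VoteRecord] = []
    preds = np.empty(len(dataset), dtype=int)
    for i in range(len(dataset)):
        seed = np.random.SeedSequence(_row_seed(rng_seed, dataset.sample_ids[i]))
        rec = predict_one(model, dataset.X[i], repeats=repeats,
                          rng_seed=seed, sigma_override=sigma_override)
        records.append(rec)
        preds[i] = rec.winner
    return preds, records
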