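"""File formats: spectra CSV, split-plan listings, model checkpoints.

The spectra table is a plain CSV: header ``sample_id, class_id, drug_id``
followed by one column per wavenumber channel labelled with its cm^-1
position to two decimals, one row per spectrum.  Channel columns must be
strictly increasing in wavenumber.  Values round-trip to 1e-9.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import ClassCatalog, SpectralDataset, WavenumberGrid
from .dataops import SplitPlan

__all__ = [
    "read_spectra",
    "write_spectra",
    "write_split",
    "read_split",
    "save_model",
    "load_model",
]

_META_COLS = ("sample_id", "class_id", "drug_id")
CHECKPOINT_FORMAT = "nirgan-checkpoint-1"


class SpectraFormatError(ValueError):
    """Malformed spectra table."""


def write_spectra(dataset: SpectralDataset, path: str | Path) -> None:
    """Write a dataset as the spectra CSV dialect (deterministic column order)."""
    labels = [f"{v:.2f}" for v in dataset.grid.channels]
    df = pd.DataFrame(dataset.X, columns=labels)
    df.insert(0, "drug_id", dataset.drug_ids)
    df.insert(0, "class_id", dataset.class_ids)
    df.insert(0, "sample_id", dataset.sample_ids)
    df.to_csv(path, index=False, float_format="%.12g")


def read_spectra(path: str | Path) -> SpectralDataset:
    """Read a spectra CSV; the wavenumber grid is inferred from the header."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SpectraFormatError(f"{path}: no spectra (empty file)") from None
    for col in _META_COLS:
        if col not in df.columns:
            raise SpectraFormatError(f"{path}: missing required column {col!r}")
    channel_cols = [c for c in df.columns if c not in _META_COLS]
    if not channel_cols:
        raise SpectraFormatError(f"{path}: no wavenumber channel columns")
    try:
        wavenumbers = np.array([float(c) for c in channel_cols])
    except ValueError as exc:
        raise SpectraFormatError(f"{path}: non-numeric channel label: {exc}") from None
    if not np.all(np.diff(wavenumbers) > 0):
        bad = int(np.argmin(np.diff(wavenumbers) > 0)) + 1
        raise SpectraFormatError(
            f"{path}: channel columns must be strictly increasing in wavenumber "
            f"(violated at column {channel_cols[bad]!r})"
        )
    if len(df) == 0:
        raise SpectraFormatError(f"{path}: no spectra (header only)")
    X = df[channel_cols].to_numpy(dtype=float)
    bad_rows = np.flatnonzero(~np.isfinite(X).all(axis=1))
    if bad_rows.size:
        lines = ", ".join(str(i + 2) for i in bad_rows[:5])  # +2: header + 1-basing
        raise SpectraFormatError(f"{path}: non-numeric or missing absorbance at line(s) {lines}")
    for col in ("class_id", "drug_id"):
        if (df[col] < 1).any():
            raise SpectraFormatError(f"{path}: {col} must be a positive integer")
    grid = WavenumberGrid(float(wavenumbers[0]), float(wavenumbers[-1]), len(wavenumbers))
    return SpectralDataset(
        X=X,
        class_ids=df["class_id"].to_numpy(dtype=int),
        drug_ids=df["drug_id"].to_numpy(dtype=int),
        grid=grid,
        sample_ids=[str(s) for s in df["sample_id"]],
    )


def write_split(split: SplitPlan, path: str | Path) -> None:
    """Plain-text split listing: header (fraction, seed) then per-class indices."""
    with open(path, "w") as fh:
        fh.write(f"# train_fraction={split.train_fraction} seed={split.rng_seed}\n")
        for cid in split.class_ids:
            tr = " ".join(map(str, split.train_indices[cid]))
            te = " ".join(map(str, split.test_indices[cid]))
            fh.write(f"class {cid} train {tr}\n")
            fh.write(f"class {cid} test {te}\n")


def read_split(path: str | Path) -> SplitPlan:
    train: dict[int, np.ndarray] = {}
    test: dict[int, np.ndarray] = {}
    with open(path) as fh:
        header = fh.readline().strip()
        parts = dict(p.split("=") for p in header.lstrip("# ").split())
        for line in fh:
            tokens = line.split()
            if len(tokens) < 3 or tokens[0] != "class":
                continue
            cid, kind = int(tokens[1]), tokens[2]
            idx = np.array([int(t) for t in tokens[3:]], dtype=int)
            (train if kind == "train" else test)[cid] = idx
    return SplitPlan(float(parts["train_fraction"]), train, test, int(parts["seed"]))


# ---------------------------------------------------------------------------
# model checkpoints


def save_model(model, path: str | Path) -> None:
    """Single-archive checkpoint: all four networks, optimizer and prior
    state, preprocessing record, catalog, and config, with a format header."""
    arrays: dict[str, np.ndarray] = {}
    for name in "EGDC":
        for key, arr in getattr(model, name).state_arrays().items():
            arrays[f"net.{name}.{key}"] = arr
        for key, arr in getattr(model, f"opt_{name}").state_arrays().items():
            arrays[f"opt.{name}.{key}"] = arr
    arrays["prior.mu"] = model.prior.mu
    arrays["prior.sigma"] = model.prior.sigma
    for i, h in enumerate(model.prior.history):
        arrays[f"prior.history.{i}"] = h
    header = {
        "format": CHECKPOINT_FORMAT,
        "config": vars(model.config),
        "catalog": [list(c) for c in model.catalog.classes],
        "offset_mean": model.offset_mean,
        "scale_mean": model.scale_mean,
        "pretrained": model.pretrained,
        "trained": model.trained,
        "n_history": len(model.prior.history),
    }
    arrays["header"] = np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_model(path: str | Path):
    """Restore a checkpoint written by :func:`save_model`."""
    from .bigan import LatentPrior, TrainConfig, build_model

    with np.load(path) as data:
        header = json.loads(bytes(data["header"]).decode())
        if header.get("format") != CHECKPOINT_FORMAT:
            raise ValueError(f"{path}: not a recognised checkpoint "
                             f"(format {header.get('format')!r})")
        config = TrainConfig(**header["config"])
        catalog = ClassCatalog(tuple(tuple(c) for c in header["catalog"]))
        model = build_model(catalog, config)
        for name in "EGDC":
            prefix = f"net.{name}."
            getattr(model, name).load_state(
                {k[len(prefix):]: data[k] for k in data.files if k.startswith(prefix)})
            oprefix = f"opt.{name}."
            getattr(model, f"opt_{name}").load_state(
                {k[len(oprefix):]: data[k] for k in data.files if k.startswith(oprefix)})
        history = [np.array(data[f"prior.history.{i}"])
                   for i in range(header["n_history"])]
        model.prior = LatentPrior(mu=np.array(data["prior.mu"]),
                                  sigma=np.array(data["prior.sigma"]),
                                  history=history, sigma_floor=config.sigma_floor)
        model.offset_mean = header["offset_mean"]
        model.scale_mean = header["scale_mean"]
        model.pretrained = header["pretrained"]
        model.trained = header["trained"]
    return model
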