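"""Core containers: wavenumber grids, class catalogs, spectral datasets.

A *spectral dataset* is a matrix of absorbance spectra (rows = samples,
columns = wavenumber channels) with a per-row manufacturer class id and a
per-row drug (product family) id.  Class ids are 1-based everywhere in the
public API, matching how manufacturer catalogs are printed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WavenumberGrid",
    "ClassCatalog",
    "SpectralDataset",
    "reference_catalog",
]


@dataclass(frozen=True)
class WavenumberGrid:
    """Evenly spaced wavenumber axis in cm^-1.

    Defaults cover the 4000-11995 cm^-1 near-infrared range at 2074
    channels, the input width of the default network architecture.
    """

    start: float = 4000.0
    end: float = 11995.0
    n_channels: int = 2074

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"grid start must be < end, got [{self.start}, {self.end}]")
        if self.n_channels < 2:
            raise ValueError(f"grid needs at least 2 channels, got {self.n_channels}")

    @property
    def channels(self) -> np.ndarray:
        """Strictly increasing channel positions (cm^-1)."""
        return np.linspace(self.start, self.end, self.n_channels)


@dataclass(frozen=True)
class ClassCatalog:
    """Ordered catalog of manufacturer classes.

    Each entry is ``(class_id, drug_id, n_samples)``.  Class ids must be
    contiguous from 1; drug ids group manufacturers into drug products.
    """

    classes: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        ids = [c[0] for c in self.classes]
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError("class_ids must be unique and contiguous from 1")
        if any(n < 1 for _, _, n in self.classes):
            raise ValueError("per-class sample counts must be positive")

    @property
    def k(self) -> int:
        """Number of classes."""
        return len(self.classes)

    @property
    def total(self) -> int:
        return int(sum(n for _, _, n in self.classes))

    @property
    def counts(self) -> np.ndarray:
        """Per-class sample counts, index 0 = class 1."""
        return np.array([n for _, _, n in self.classes], dtype=int)

    @property
    def drug_ids(self) -> np.ndarray:
        """Per-class drug id, index 0 = class 1."""
        return np.array([d for _, d, _ in self.classes], dtype=int)

    @property
    def n_drugs(self) -> int:
        return int(len(np.unique(self.drug_ids)))

    def drug_of(self, class_id: int) -> int:
        return int(self.classes[class_id - 1][1])


# Per-manufacturer sample counts of the 1721-spectrum benchmark collection:
# four drug products (metformin hydrochloride, chlorpromazine hydrochloride,
# chlorphenamine maleate, cefuroxime axetil tablets) from 29 manufacturers.
_REFERENCE_COUNTS = (
    94, 48, 67, 21, 48, 64, 27, 35, 48, 24, 68, 97, 97, 97,   # drug 1: classes 1-14
    59, 94, 58, 135, 49,                                       # drug 2: classes 15-19
    39, 45, 36, 39, 94,                                        # drug 3: classes 20-24
    56, 29, 27, 89, 37,                                        # drug 4: classes 25-29
)
_REFERENCE_DRUGS = (1,) * 14 + (2,) * 5 + (3,) * 5 + (4,) * 5


def reference_catalog() -> ClassCatalog:
    """The bundled 29-manufacturer benchmark catalog (1721 samples total).

    Manufacturer counts range from 21 to 135 and follow a long-tail
    distribution; classes 1-14 belong to drug 1, 15-19 to drug 2,
    20-24 to drug 3, 25-29 to drug 4.
    """
    return ClassCatalog(
        tuple(
            (i + 1, _REFERENCE_DRUGS[i], _REFERENCE_COUNTS[i])
            for i in range(len(_REFERENCE_COUNTS))
        )
    )


@dataclass
class SpectralDataset:
    """N spectra on a shared wavenumber grid with class and drug labels."""

    X: np.ndarray                 # (N, L) absorbance matrix
    class_ids: np.ndarray         # (N,) 1-based manufacturer class per row
    drug_ids: np.ndarray          # (N,) 1-based drug product per row
    grid: WavenumberGrid
    sample_ids: list[str] = field(default_factory=list)
    catalog: ClassCatalog | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.class_ids = np.asarray(self.class_ids, dtype=int)
        self.drug_ids = np.asarray(self.drug_ids, dtype=int)
        n, L = self.X.shape
        if len(self.class_ids) != n or len(self.drug_ids) != n:
            raise ValueError("label lengths must match the number of spectra")
        if L != self.grid.n_channels:
            raise ValueError(
                f"spectra have {L} channels but grid declares {self.grid.n_channels}"
            )
        if not np.all(np.isfinite(self.X)):
            raise ValueError("spectra must be finite")
        if not self.sample_ids:
            self.sample_ids = [f"S{i:05d}" for i in range(n)]
        elif len(self.sample_ids) != n:
            raise ValueError("sample_ids length must match the number of spectra")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_channels(self) -> int:
        return self.X.shape[1]

    def class_indices(self, class_id: int) -> np.ndarray:
        """Row indices of one class, in dataset order."""
        return np.flatnonzero(self.class_ids == class_id)

    def subset(self, rows: np.ndarray) -> "SpectralDataset":
        rows = np.asarray(rows, dtype=int)
        return SpectralDataset(
            X=self.X[rows],
            class_ids=self.class_ids[rows],
            drug_ids=self.drug_ids[rows],
            grid=self.grid,
            sample_ids=[self.sample_ids[i] for i in rows],
            catalog=self.catalog,
        )
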