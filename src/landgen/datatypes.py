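"""Shared data model for the landscape-genomic pipeline.

Genotypes are biallelic SNPs stored as alt-allele dosages in {0, 1, 2} with no
missing entries; coordinates are planar kilometres; land cover is a categorical
raster with a resistance model mapping classes to values on a 1 (no resistance)
to 100 (maximum resistance) scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

# land-cover class codes
FOREST = 1
MANAGED_VEGETATION = 2
URBAN = 3
WATER = 4

CLASS_NAMES = {
    FOREST: "forest",
    MANAGED_VEGETATION: "managed_vegetation",
    URBAN: "urban",
    WATER: "water",
}


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class PloidyError(ValueError):
    """A locus violates the biallelic-diploid assumption."""


@dataclass
class GenotypeMatrix:
    """n individuals x L biallelic loci, coded as alt-allele counts {0,1,2}.

    The matrix is complete by construction: loci with missing genotypes are
    excluded upstream, mirroring SNP matrices filtered for no missing data.
    """

    individuals: list[str]
    loci: list[str]
    G: np.ndarray  # (n, L) int8/int64
    ploidy: int = 2

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G)
        n, L = self.G.shape
        if n < 2 or L < 1:
            raise ValueError(f"need n >= 2 individuals and L >= 1 loci, got {n}x{L}")
        if len(self.individuals) != n or len(self.loci) != L:
            raise ValueError("ID lists do not match matrix shape")
        if len(set(self.individuals)) != n:
            raise ValueError("duplicate individual IDs")
        if not np.isin(self.G, (0, 1, 2)).all():
            raise ValueError("genotypes must be alt-allele dosages in {0,1,2}")

    @property
    def n(self) -> int:
        return self.G.shape[0]

    @property
    def L(self) -> int:
        return self.G.shape[1]

    def alt_freqs(self) -> np.ndarray:
        """Sample alt-allele frequency per locus."""
        return self.G.mean(axis=0) / 2.0

    def polymorphic_mask(self) -> np.ndarray:
        p = self.alt_freqs()
        return (p > 0) & (p < 1)

    def subset(self, individuals: Sequence[str] | None = None,
               loci_idx: Sequence[int] | None = None) -> "GenotypeMatrix":
        rows = (
            np.arange(self.n)
            if individuals is None
            else np.array([self.individuals.index(i) for i in individuals])
        )
        cols = np.arange(self.L) if loci_idx is None else np.asarray(loci_idx)
        return GenotypeMatrix(
            [self.individuals[i] for i in rows],
            [self.loci[j] for j in cols],
            self.G[np.ix_(rows, cols)],
        )


@dataclass
class SampleFrame:
    """Per-individual metadata: planar km coordinates and subpopulation label."""

    table: pd.DataFrame  # columns: id, x_km, y_km, pop

    def __post_init__(self) -> None:
        required = {"id", "pop"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"SampleFrame needs columns {required}")
        if self.table["id"].duplicated().any():
            raise ValueError("duplicate sample IDs")
        for c in ("x_km", "y_km"):
            if c in self.table.columns and not np.isfinite(
                self.table[c].to_numpy(float)
            ).all():
                raise ValueError(f"non-finite coordinates in {c}")
        self.table = self.table.reset_index(drop=True)

    @property
    def ids(self) -> list[str]:
        return list(self.table["id"])

    @property
    def pops(self) -> np.ndarray:
        return self.table["pop"].to_numpy()

    def coords(self) -> np.ndarray:
        return self.table[["x_km", "y_km"]].to_numpy(float)

    def aligned_to(self, genotypes: GenotypeMatrix) -> "SampleFrame":
        """Reorder rows to match the genotype matrix; IDs must coincide."""
        if set(self.ids) != set(genotypes.individuals):
            raise ValueError("sample IDs do not match genotype matrix")
        t = self.table.set_index("id").loc[genotypes.individuals].reset_index()
        return SampleFrame(t)


@dataclass
class LandscapeRaster:
    """Categorical land-cover grid (row 0 = northernmost row)."""

    classes: np.ndarray  # (nrows, ncols) int
    cellsize_km: float
    xllcorner: float = 0.0
    yllcorner: float = 0.0

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=int)
        if self.cellsize_km <= 0:
            raise ValueError("cellsize must be positive")
        known = set(CLASS_NAMES)
        present = set(np.unique(self.classes).tolist())
        if not present.issubset(known):
            raise ValueError(f"unknown land-cover codes: {present - known}")

    @property
    def nrows(self) -> int:
        return self.classes.shape[0]

    @property
    def ncols(self) -> int:
        return self.classes.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """x, y (km) of every cell center, row-major."""
        rows, cols = np.indices(self.classes.shape)
        x = self.xllcorner + (cols + 0.5) * self.cellsize_km
        y = self.yllcorner + (self.nrows - rows - 0.5) * self.cellsize_km
        return x.ravel(), y.ravel()

    def cell_of(self, x_km: float, y_km: float) -> tuple[int, int]:
        col = int((x_km - self.xllcorner) / self.cellsize_km)
        row = self.nrows - 1 - int((y_km - self.yllcorner) / self.cellsize_km)
        row = min(max(row, 0), self.nrows - 1)
        col = min(max(col, 0), self.ncols - 1)
        return row, col


@dataclass
class ResistanceModel:
    """Map from land-cover class to resistance on the 1..100 scale."""

    values: Mapping[int, float]

    def __post_init__(self) -> None:
        for k, v in self.values.items():
            if not 1.0 <= v <= 100.0:
                raise ValueError(
                    f"resistance for class {CLASS_NAMES.get(k, k)} out of [1,100]: {v}"
                )

    def __getitem__(self, cls: int) -> float:
        return self.values[cls]

    @property
    def urban(self) -> float:
        return self.values[URBAN]

    @property
    def managed_vegetation(self) -> float:
        return self.values[MANAGED_VEGETATION]


@dataclass
class PairwiseMatrix:
    """Symmetric labelled pairwise matrix with a kind tag."""

    labels: list[str]
    values: np.ndarray
    kind: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValueError("matrix shape does not match labels")
        finite = np.isfinite(self.values)
        if not np.allclose(
            self.values[finite & finite.T],
            self.values.T[finite & finite.T],
            atol=1e-8,
        ):
            raise ValueError("matrix is not symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def pair(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])
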