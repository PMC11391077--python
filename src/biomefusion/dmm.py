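"""Discrete Manhattan Metric: model-vs-pollen biome agreement scoring.

The DMM of a simulated biome map against a set of pollen observations is
the mean, over sites, of a pairwise biome dissimilarity looked up in a
biome-distance matrix with entries in [0, 1]: 0 for agreement at a site,
1 for the most dissimilar biomes, so an overall score of 0 is complete
agreement and 1 complete disagreement.  Constant single-biome null
models give the baseline against which an improvement percentage is
quoted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .correction import PollenSite
from .grid import PHYSICAL_BOUNDS, VARIABLES
from .scheme import BiomeMap, BiomeScheme

__all__ = [
    "BiomeDistanceMatrix",
    "distance_matrix_from_scheme",
    "uniform_distance_matrix",
    "dmm_score",
    "null_model_score",
    "improvement",
]


@dataclass(frozen=True)
class BiomeDistanceMatrix:
    """Symmetric biome dissimilarity with zero diagonal, entries in [0,1]."""

    codes: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.codes), len(self.codes)):
            raise ValueError("matrix shape does not match code list")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (m < -1e-12).any() or (m > 1 + 1e-12).any():
            raise ValueError("distance matrix entries must lie in [0, 1]")
        object.__setattr__(self, "matrix", m)

    def distance(self, a: str, b: str) -> float:
        try:
            i, j = self.codes.index(a), self.codes.index(b)
        except ValueError as exc:
            raise KeyError(f"biome code not in distance matrix: {exc}") from None
        return float(self.matrix[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.codes), columns=list(self.codes))

    @classmethod
    def from_csv(cls, path) -> "BiomeDistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(codes=tuple(df.columns), matrix=df.to_numpy(dtype=float))

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)


def uniform_distance_matrix(codes: Iterable[str]) -> BiomeDistanceMatrix:
    """Fallback matrix: 1 for every off-diagonal pair (pure mismatch rate)."""
    codes = tuple(codes)
    m = 1.0 - np.eye(len(codes))
    return BiomeDistanceMatrix(codes=codes, matrix=m)


def distance_matrix_from_scheme(scheme: BiomeScheme) -> BiomeDistanceMatrix:
    """Biome distances derived from the scheme's bioclimatic ranges.

    The distance between two biomes is the mean over the six variables
    of the Jaccard distance ``1 - |A & B| / |A | B|`` between their
    defining intervals, capped to the physical bounds.  Two biomes with
    identical boxes score 0; biomes disjoint in every variable — as
    opposite as the scheme allows — score 1.
    """
    n = len(scheme)
    m = np.zeros((n, n))
    for i, bi in enumerate(scheme.biomes):
        for j in range(i + 1, n):
            bj = scheme.biomes[j]
            ds = []
            for v in VARIABLES:
                lo1, hi1 = bi.intervals[v].capped(PHYSICAL_BOUNDS[v])
                lo2, hi2 = bj.intervals[v].capped(PHYSICAL_BOUNDS[v])
                inter = max(0.0, min(hi1, hi2) - max(lo1, lo2))
                union = max(hi1, hi2) - min(lo1, lo2)
                ds.append(0.0 if union <= 0 else 1.0 - inter / union)
            m[i, j] = m[j, i] = float(np.mean(ds))
    return BiomeDistanceMatrix(codes=tuple(scheme.codes), matrix=m)


def _site_cells(bmap: BiomeMap, sites: Sequence[PollenSite]) -> list[str]:
    simulated = []
    bad = []
    for s in sites:
        if not bmap.geometry.contains(s.lon, s.lat):
            bad.append(s.site_id or f"({s.lon}, {s.lat})")
            continue
        r, c = bmap.geometry.cell_of(s.lon, s.lat)
        if bmap.codes[r, c] < 0:
            bad.append(s.site_id or f"({s.lon}, {s.lat})")
            continue
        simulated.append(bmap.code_at(r, c))
    if bad:
        raise ValueError(f"sites over masked or out-of-domain cells: {bad}")
    return simulated


def dmm_score(bmap: BiomeMap, sites: Sequence[PollenSite], D: BiomeDistanceMatrix) -> float:
    """Mean biome distance between the simulated map and the observations."""
    if not sites:
        raise ValueError("no sites to score")
    simulated = _site_cells(bmap, sites)
    return float(
        np.mean([D.distance(sim, s.observed_biome) for sim, s in zip(simulated, sites)])
    )


def null_model_score(
    constant_biome: str, sites: Sequence[PollenSite], D: BiomeDistanceMatrix
) -> float:
    """DMM of a map constant at one biome — a single-value null model."""
    if not sites:
        raise ValueError("no sites to score")
    if constant_biome not in D.codes:
        raise KeyError(f"unknown biome code {constant_biome!r}")
    return float(np.mean([D.distance(constant_biome, s.observed_biome) for s in sites]))


def improvement(score: float, null_scores: Iterable[float]) -> float:
    """Percent improvement of a score over the best single-value null.

    ``100 * (min(nulls) - score) / min(nulls)``; scores are distances,
    so smaller is better and 100 means perfect agreement.
    """
    nulls = list(null_scores)
    if not nulls:
        raise ValueError("need at least one null score")
    best = min(nulls)
    if best <= 0:
        raise ZeroDivisionError("best null score is zero; improvement undefined")
    return 100.0 * (best - score) / best
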