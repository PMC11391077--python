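"""Biomisation: threshold-scheme classification of bioclimatic variables.

A :class:`BiomeScheme` is an ordered list of biome definitions, each a box
of per-variable intervals over the six bioclimatic variables.  Intervals
are closed below and open above (``lo <= x < hi``) so shared thresholds
never produce ties; the default scheme's boxes are pairwise disjoint and
jointly cover the attainable variable space.

The scheme is data, not code: it ships as a YAML config whose interval
endpoints may reference named thresholds, and :func:`scale_scheme`
rewrites those thresholds to build the sensitivity variants (the cover
and height boundaries between desert/grass/savanna/tall-savanna/forest).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import yaml

from .grid import PHYSICAL_BOUNDS, VARIABLES, BioclimGrid, ConfigurationError, GridGeometry

__all__ = [
    "Interval",
    "BiomeDef",
    "BiomeScheme",
    "BiomeMap",
    "ClassificationError",
    "classify",
    "biomise",
    "biome_ranges",
    "scale_scheme",
    "load_scheme",
    "default_scheme",
]


class ClassificationError(ValueError):
    """No biome in the scheme matches a set of variable values."""


@dataclass(frozen=True)
class Interval:
    """Half-open interval [lo, hi); infinite endpoints mean unbounded."""

    lo: float = -np.inf
    hi: float = np.inf

    def __post_init__(self) -> None:
        if not self.lo <= self.hi:
            raise ConfigurationError(f"interval lo {self.lo} > hi {self.hi}")

    def contains(self, x) -> np.ndarray:
        return (np.asarray(x) >= self.lo) & (np.asarray(x) < self.hi)

    def capped(self, bounds: tuple[float, float]) -> tuple[float, float]:
        """Endpoints clipped to physical bounds (for midpoints/distances)."""
        return (max(self.lo, bounds[0]), min(self.hi, bounds[1]))

    def midpoint(self, bounds: tuple[float, float]) -> float:
        lo, hi = self.capped(bounds)
        return 0.5 * (lo + hi)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.lo}, {self.hi})"


@dataclass(frozen=True)
class BiomeDef:
    code: str
    name: str
    intervals: Mapping[str, Interval]  # one entry per variable in VARIABLES

    def matches(self, values: Mapping[str, float]) -> bool:
        return all(self.intervals[v].contains(values[v]) for v in VARIABLES)


class BiomeScheme:
    """Ordered biome definitions plus the named thresholds they reference."""

    def __init__(self, biomes: Sequence[BiomeDef], thresholds: Mapping[str, float]):
        codes = [b.code for b in biomes]
        if len(set(codes)) != len(codes):
            raise ConfigurationError("duplicate biome codes in scheme")
        self.biomes = list(biomes)
        self.thresholds = dict(thresholds)
        self._index = {b.code: i for i, b in enumerate(self.biomes)}

    @property
    def codes(self) -> list[str]:
        return [b.code for b in self.biomes]

    def __len__(self) -> int:
        return len(self.biomes)

    def __getitem__(self, code: str) -> BiomeDef:
        try:
            return self.biomes[self._index[code]]
        except KeyError:
            raise KeyError(f"unknown biome code {code!r}") from None

    def code_index(self, code: str) -> int:
        if code not in self._index:
            raise KeyError(f"unknown biome code {code!r}")
        return self._index[code]

    def digest(self) -> str:
        """Short stable hash of the scheme content, for provenance stamps."""
        import hashlib

        parts = []
        for b in self.biomes:
            parts.append(b.code)
            for v in VARIABLES:
                iv = b.intervals[v]
                parts.append(f"{iv.lo!r}:{iv.hi!r}")
        return hashlib.sha256("|".join(parts).encode()).hexdigest()[:12]

    # --- construction from config ------------------------------------

    @classmethod
    def from_config(cls, config: Mapping) -> "BiomeScheme":
        thresholds = {k: float(v) for k, v in config.get("thresholds", {}).items()}

        def resolve(endpoint, default: float) -> float:
            if endpoint is None:
                return default
            if isinstance(endpoint, str):
                if endpoint not in thresholds:
                    raise ConfigurationError(f"unknown threshold name {endpoint!r}")
                return thresholds[endpoint]
            return float(endpoint)

        biomes = []
        for entry in config["biomes"]:
            intervals = {}
            declared = entry.get("intervals", {})
            for v in VARIABLES:
                if v in declared:
                    lo_raw, hi_raw = declared[v]
                    intervals[v] = Interval(
                        resolve(lo_raw, -np.inf), resolve(hi_raw, np.inf)
                    )
                else:
                    intervals[v] = Interval()
            biomes.append(BiomeDef(code=entry["code"], name=entry.get("name", entry["code"]), intervals=intervals))
        return cls(biomes, thresholds)

    def to_config(self) -> dict:
        out = {"thresholds": dict(self.thresholds), "biomes": []}
        for b in self.biomes:
            iv = {}
            for v in VARIABLES:
                lo, hi = b.intervals[v].lo, b.intervals[v].hi
                if np.isfinite(lo) or np.isfinite(hi):
                    iv[v] = [
                        None if not np.isfinite(lo) else float(lo),
                        None if not np.isfinite(hi) else float(hi),
                    ]
            out["biomes"].append({"code": b.code, "name": b.name, "intervals": iv})
        return out


def load_scheme(path) -> BiomeScheme:
    with open(path) as fh:
        return BiomeScheme.from_config(yaml.safe_load(fh))


def default_scheme() -> BiomeScheme:
    """The scheme shipped with the package (16 biomes incl. WTs)."""
    ref = importlib.resources.files("biomefusion.data") / "biome_scheme.yml"
    return BiomeScheme.from_config(yaml.safe_load(ref.read_text()))


def classify(values: Mapping[str, float], scheme: BiomeScheme) -> str:
    """Classify one six-variable tuple; first matching biome wins."""
    for b in scheme.biomes:
        if b.matches(values):
            return b.code
    raise ClassificationError(f"no biome matches values {dict(values)!r}")


def classify_arrays(fields: Mapping[str, np.ndarray], scheme: BiomeScheme) -> np.ndarray:
    """Vectorised classify over arrays; returns int indices into scheme.codes."""
    shape = np.asarray(fields[VARIABLES[0]]).shape
    out = np.full(shape, -1, dtype=np.int16)
    unassigned = np.ones(shape, dtype=bool)
    for i, b in enumerate(scheme.biomes):
        if not unassigned.any():
            break
        match = unassigned.copy()
        for v in VARIABLES:
            match &= b.intervals[v].contains(fields[v])
        out[match] = i
        unassigned &= ~match
    return out


@dataclass
class BiomeMap:
    """Per-cell biome assignment: integer codes indexing ``scheme_codes``."""

    geometry: GridGeometry
    codes: np.ndarray  # int16, -1 over masked cells
    scheme_codes: list[str]

    @property
    def mask(self) -> np.ndarray:
        return self.codes >= 0

    def code_at(self, row: int, col: int) -> str:
        idx = int(self.codes[row, col])
        if idx < 0:
            raise ValueError(f"cell ({row}, {col}) is masked")
        return self.scheme_codes[idx]

    def to_dataset(self):
        import xarray as xr

        ds = xr.Dataset(
            {"biome": (("lat", "lon"), self.codes.astype(np.int16))},
            coords={"lat": self.geometry.lats, "lon": self.geometry.lons},
        )
        ds["biome"].attrs["flag_values"] = list(range(len(self.scheme_codes)))
        ds["biome"].attrs["flag_meanings"] = " ".join(self.scheme_codes)
        ds.attrs["resolution"] = self.geometry.resolution
        return ds

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")


def biomise(grid: BioclimGrid, scheme: BiomeScheme) -> BiomeMap:
    """Classify every land cell of a grid; masked cells stay masked."""
    idx = classify_arrays(grid.fields, scheme)
    bad = (idx < 0) & grid.mask
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ClassificationError(
            f"no biome matches cell (row={r}, col={c}) values {grid.values_at(r, c)!r}"
        )
    idx = idx.copy()
    idx[~grid.mask] = -1
    return BiomeMap(geometry=grid.geometry, codes=idx, scheme_codes=scheme.codes)


def biome_ranges(code: str, scheme: BiomeScheme) -> dict[str, Interval]:
    """The six per-variable intervals defining a biome.

    These are the target ranges the bias correction pulls model output
    toward at pollen sites.
    """
    return dict(scheme[code].intervals)


def scale_scheme(
    scheme: BiomeScheme,
    fpc_thresholds: tuple[float, float] = (0.3, 0.6),
    h_thresholds: tuple[float, float] = (5.0, 10.0),
) -> BiomeScheme:
    """Scheme with rescaled cover and height boundaries.

    ``fpc_thresholds`` replaces the (desert/grass, grass/forest) cover
    boundaries and ``h_thresholds`` the (savanna/tall-savanna,
    tall-savanna/forest) height boundaries; everything else is untouched.
    Used for the two threshold-sensitivity variants (0.2/0.4 with 2.5/5,
    and 0.5/0.75 with 10/20).
    """
    f_lo, f_hi = map(float, fpc_thresholds)
    h_lo, h_hi = map(float, h_thresholds)
    if not 0 < f_lo < f_hi < 1:
        raise ConfigurationError("fpc thresholds must satisfy 0 < lo < hi < 1")
    if not 0 < h_lo < h_hi < scheme.thresholds.get("h_max", 130.0):
        raise ConfigurationError("height thresholds must be strictly ordered within (0, h_max)")
    old = {
        "fpc_arid": scheme.thresholds["fpc_arid"],
        "fpc_forest": scheme.thresholds["fpc_forest"],
        "h_savanna": scheme.thresholds["h_savanna"],
        "h_forest": scheme.thresholds["h_forest"],
    }
    new = {"fpc_arid": f_lo, "fpc_forest": f_hi, "h_savanna": h_lo, "h_forest": h_hi}
    var_of = {"fpc_arid": "fpc", "fpc_forest": "fpc", "h_savanna": "height", "h_forest": "height"}

    biomes = []
    for b in scheme.biomes:
        intervals = {}
        for v in VARIABLES:
            lo, hi = b.intervals[v].lo, b.intervals[v].hi
            for key, val in old.items():
                if var_of[key] != v:
                    continue
                if lo == val:
                    lo = new[key]
                if hi == val:
                    hi = new[key]
            intervals[v] = Interval(lo, hi)
        biomes.append(BiomeDef(code=b.code, name=b.name, intervals=intervals))
    thresholds = dict(scheme.thresholds)
    thresholds.update(new)
    return BiomeScheme(biomes, thresholds)
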