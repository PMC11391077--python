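"""Pollen-anchored bias correction of gridded vegetation-model output.

At each pollen site the model's six transformed variable values are
compared with the transformed bioclimatic range of the biome the pollen
record observed there.  The signed distance to the closest range
boundary (zero when the model already lies inside the range) becomes an
anchor; a thin-plate spline surface through the anchors extrapolates the
correction across the grid, and the surface is subtracted from the
transformed field before back-transforming.  Each of the six variables
is corrected independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grid import PHYSICAL_BOUNDS, VARIABLES, BioclimGrid
from .scheme import BiomeScheme, Interval
from .transforms import VariableTransform, default_transforms
from .tps import CorrectionSurface, fit_tps

__all__ = [
    "PollenSite",
    "read_sites_csv",
    "write_sites_csv",
    "site_correction",
    "transformed_interval",
    "correct_grid",
]


@dataclass(frozen=True)
class PollenSite:
    """A pollen-core location with its observed (pre-assigned) biome."""

    lon: float
    lat: float
    observed_biome: str
    site_id: str = ""


def read_sites_csv(path) -> list[PollenSite]:
    df = pd.read_csv(path)
    return [
        PollenSite(
            lon=float(r["lon"]),
            lat=float(r["lat"]),
            observed_biome=str(r["biome"]),
            site_id=str(r.get("site_id", i)),
        )
        for i, r in df.iterrows()
    ]


def write_sites_csv(sites: Sequence[PollenSite], path) -> None:
    pd.DataFrame(
        {
            "lon": [s.lon for s in sites],
            "lat": [s.lat for s in sites],
            "biome": [s.observed_biome for s in sites],
            "site_id": [s.site_id for s in sites],
        }
    ).to_csv(path, index=False)


def site_correction(model_value_t: float, target_range_t: tuple[float, float], margin: float = 0.0) -> float:
    """Signed correction moving a transformed value to its target range.

    Returns 0 when the value already lies inside ``[lo, hi)`` (ranges
    follow the scheme's closed-below, open-above convention); otherwise
    ``value - hi`` (above) or ``value - lo`` (below), so that
    ``value - correction`` lands on the nearest boundary.  A positive
    ``margin`` lands the value that far inside the boundary instead,
    which keeps re-classification off the half-open upper edges.
    """
    lo, hi = target_range_t
    if not lo <= hi:
        raise ValueError(f"empty target range ({lo}, {hi})")
    if model_value_t >= hi:
        return model_value_t - (hi - margin)
    if model_value_t < lo:
        return model_value_t - (lo + margin)
    return 0.0


def transformed_interval(
    interval: Interval, transform: VariableTransform, bounds: tuple[float, float]
) -> tuple[float, float]:
    """A biome interval mapped to transformed space.

    Endpoints at or beyond the physical bounds are unbounded in
    transformed space (the transform diverges at the limits), so only
    interior thresholds constrain the correction.
    """
    lo_phys, hi_phys = bounds
    lo = -np.inf if interval.lo <= lo_phys else float(transform.apply(interval.lo))
    hi = np.inf if interval.hi >= hi_phys else float(transform.apply(interval.hi))
    return lo, hi


def correct_grid(
    model: BioclimGrid,
    sites: Sequence[PollenSite],
    scheme: BiomeScheme,
    transforms: Mapping[str, VariableTransform] | None = None,
    lam: float | None = 0.0,
    margin: float = 1e-6,
    return_surfaces: bool = False,
):
    """Bias-correct a model grid against pollen-site biome observations.

    For each variable: transform the field, compute per-site corrections
    against the observed biome's transformed range, fit a thin-plate
    spline through them, subtract the surface from the transformed field,
    and back-transform with clipping to physical bounds.

    Parameters
    ----------
    lam:
        Spline smoothing; 0 (default) interpolates anchors exactly,
        ``None`` selects by generalized cross-validation.
    margin:
        Transformed-space distance inside the range boundary at which
        out-of-range anchors land (keeps corrected cells strictly inside
        the observed biome's half-open intervals).
    return_surfaces:
        Also return the per-variable :class:`CorrectionSurface` dict.
    """
    if transforms is None:
        transforms = default_transforms()
    geometry = model.geometry

    cells: list[tuple[int, int]] = []
    biomes: list[str] = []
    for site in sites:
        if not geometry.contains(site.lon, site.lat):
            raise ValueError(f"site {site.site_id!r} at ({site.lon}, {site.lat}) outside grid domain")
        r, c = geometry.cell_of(site.lon, site.lat)
        if not model.mask[r, c]:
            raise ValueError(f"site {site.site_id!r} falls on a masked cell")
        scheme[site.observed_biome]  # raises on unknown code
        cells.append((r, c))
        biomes.append(site.observed_biome)

    lon_grid, lat_grid = geometry.meshgrid()
    corrected_fields: dict[str, np.ndarray] = {}
    surfaces: dict[str, CorrectionSurface] = {}

    for var in VARIABLES:
        tr = transforms[var]
        field_t = tr.apply(tr.clip_physical(model.fields[var]))

        # one anchor per grid cell; duplicate-cell sites averaged
        per_cell: dict[tuple[int, int], list[float]] = {}
        for (r, c), biome in zip(cells, biomes):
            rng = transformed_interval(scheme[biome].intervals[var], tr, PHYSICAL_BOUNDS[var])
            corr = site_correction(float(field_t[r, c]), rng, margin=margin)
            per_cell.setdefault((r, c), []).append(corr)

        anchor_cells = sorted(per_cell)
        anchors = np.array(
            [[geometry.lons[c], geometry.lats[r]] for r, c in anchor_cells]
        )
        values = np.array([np.mean(per_cell[rc]) for rc in anchor_cells])

        surface = fit_tps(anchors, values, lam=lam, variable=var)
        corrected_t = field_t - surface(lon_grid, lat_grid)
        corrected_fields[var] = tr.clip_physical(tr.invert(corrected_t))
        surfaces[var] = surface

    corrected = BioclimGrid(geometry=geometry, fields=corrected_fields, mask=model.mask.copy())
    if return_surfaces:
        return corrected, surfaces
    return corrected
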