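"""Synthetic DVM-like grids, injected bias, and pollen-site observations.

The generator emulates the study setting end-to-end with a known ground
truth: six spatially smooth bioclimatic fields over a tropical
South-America-like domain, a smooth "model" bias injected in the same
transformed space the correction operates in, and point observations
whose biome labels derive from the unbiased truth.  Every downstream
stage (biomisation, bias correction, clustering, fragmentation, DMM
scoring) is testable against the truth without any external data.

Fields are built in transformed space as a low-order trend surface plus
Gaussian-filtered white noise, then back-transformed — the simplest
construction with controllable spatial autocorrelation that respects
the physical bounds for any seed.  All randomness flows from the
scenario's single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .correction import PollenSite
from .grid import BioclimGrid, ConfigurationError, GridGeometry, VARIABLES
from .scheme import BiomeScheme, biomise
from .transforms import default_transforms

__all__ = [
    "TrendParams",
    "BiasSpec",
    "SyntheticScenario",
    "default_scenario",
    "generate_truth",
    "apply_bias",
    "sample_pollen_sites",
]


@dataclass(frozen=True)
class TrendParams:
    """Transformed-space mean surface plus spatial noise for one variable.

    The trend is ``base + grad_lon*(x - 1/2) + grad_lat*(y - 1/2)`` with
    x, y the fractional position in the domain (0 at the W/S edge).
    Noise is white noise smoothed with a Gaussian of ``noise_sigma``
    cells, rescaled to standard deviation ``noise_sd``.
    """

    base: float
    grad_lon: float = 0.0
    grad_lat: float = 0.0
    noise_sd: float = 0.0
    noise_sigma: float = 5.0


@dataclass(frozen=True)
class BiasSpec:
    """Smooth transformed-space bias for one variable.

    ``bias = offset + amplitude * g`` where g is Gaussian-filtered white
    noise with correlation length ``length_scale`` (fraction of the
    domain's longitudinal extent) rescaled to zero mean and unit RMS.
    """

    amplitude: float = 0.0
    offset: float = 0.0
    length_scale: float = 0.33


@dataclass(frozen=True)
class SyntheticScenario:
    geometry: GridGeometry
    field_params: Mapping[str, TrendParams]
    bias_params: Mapping[str, BiasSpec]
    n_sites: int = 42
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.n_sites < 3:
            raise ConfigurationError("n_sites must be >= 3 (spline needs non-collinear anchors)")
        for var, spec in self.bias_params.items():
            if not (np.isfinite(spec.amplitude) and np.isfinite(spec.offset)):
                raise ConfigurationError(f"non-finite bias amplitude/offset for {var!r}")
        missing = set(VARIABLES) - set(self.field_params)
        if missing:
            raise ConfigurationError(f"field_params missing variables: {sorted(missing)}")


#: Default trends (transformed units): forests in the moist north-west
#: grading through woodland/tall savanna and savanna to open shrubland in
#: the drier south-east, with tropical composition and warm GDD across
#: the whole domain.
DEFAULT_FIELD_PARAMS: dict[str, TrendParams] = {
    "fpc": TrendParams(base=0.8, grad_lon=-2.5, grad_lat=1.0, noise_sd=0.4),
    "height": TrendParams(base=-2.6, grad_lon=-1.2, grad_lat=0.7, noise_sd=0.35),
    "evergreen": TrendParams(base=0.5, grad_lon=-0.8, grad_lat=0.5, noise_sd=0.3),
    "tropical": TrendParams(base=1.2, grad_lon=0.0, grad_lat=0.8, noise_sd=0.2),
    "temperate": TrendParams(base=-1.2, grad_lon=0.0, grad_lat=-0.5, noise_sd=0.2),
    "gdd": TrendParams(base=8.6, grad_lon=0.0, grad_lat=0.5, noise_sd=0.1),
}

#: Default bias: strongest on height and cover (the variables that drive
#: the forest/savanna structure), weaker on composition and GDD.
DEFAULT_BIAS_PARAMS: dict[str, BiasSpec] = {
    "fpc": BiasSpec(amplitude=1.0),
    "height": BiasSpec(amplitude=1.0),
    "evergreen": BiasSpec(amplitude=0.2),
    "tropical": BiasSpec(amplitude=0.2),
    "temperate": BiasSpec(amplitude=0.2),
    "gdd": BiasSpec(amplitude=0.1),
}


def default_scenario(
    seed: int = 0,
    n_sites: int = 42,
    geometry: GridGeometry | None = None,
    bias_params: Mapping[str, BiasSpec] | None = None,
    field_params: Mapping[str, TrendParams] | None = None,
    stratified: bool = True,
) -> SyntheticScenario:
    """Study-like scenario: ~85-30 degW, 25 degS-12 degN at 0.5 degrees."""
    if geometry is None:
        geometry = GridGeometry(lon_min=-85, lon_max=-30, lat_min=-25, lat_max=12, resolution=0.5)
    return SyntheticScenario(
        geometry=geometry,
        field_params=dict(field_params or DEFAULT_FIELD_PARAMS),
        bias_params=dict(bias_params or DEFAULT_BIAS_PARAMS),
        n_sites=n_sites,
        seed=seed,
        stratified=stratified,
    )


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Gaussian-filtered white noise, zero mean and unit standard deviation."""
    raw = rng.standard_normal(shape)
    sm = gaussian_filter(raw, sigma=sigma, mode="nearest")
    sm -= sm.mean()
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def _trend_surface(params: TrendParams, geometry: GridGeometry) -> np.ndarray:
    nx, ny = geometry.n_lon, geometry.n_lat
    x = (np.arange(nx) + 0.5) / nx - 0.5
    y = (np.arange(ny) + 0.5) / ny - 0.5
    xx, yy = np.meshgrid(x, y)
    return params.base + params.grad_lon * xx + params.grad_lat * yy


def generate_truth(scenario: SyntheticScenario) -> BioclimGrid:
    """Generate the unbiased six-field truth grid for a scenario."""
    transforms = default_transforms()
    fields: dict[str, np.ndarray] = {}
    for i, var in enumerate(VARIABLES):
        params = scenario.field_params[var]
        t = _trend_surface(params, scenario.geometry)
        if params.noise_sd > 0:
            rng = np.random.default_rng([scenario.seed, i])
            t = t + params.noise_sd * _smooth_noise(
                rng, scenario.geometry.shape, params.noise_sigma
            )
        fields[var] = transforms[var].invert(t)
    grid = BioclimGrid(geometry=scenario.geometry, fields=fields)
    grid.validate_bounds()
    return grid


def bias_fields(scenario: SyntheticScenario) -> dict[str, np.ndarray]:
    """The injected transformed-space bias surface for each variable."""
    out: dict[str, np.ndarray] = {}
    nx = scenario.geometry.n_lon
    for i, var in enumerate(VARIABLES):
        spec = scenario.bias_params.get(var, BiasSpec())
        b = np.full(scenario.geometry.shape, spec.offset, dtype=float)
        if spec.amplitude != 0.0:
            rng = np.random.default_rng([scenario.seed, 100 + i])
            sigma = max(spec.length_scale * nx / 2.0, 1.0)
            b = b + spec.amplitude * _smooth_noise(rng, scenario.geometry.shape, sigma)
        out[var] = b
    return out


def apply_bias(truth: BioclimGrid, scenario: SyntheticScenario) -> BioclimGrid:
    """Return "model" fields: back-transform(transform(truth) + bias).

    The bias lives in the same transformed (logit/log) space the
    correction operates in, so parameter-recovery experiments are exact
    in the space the method works in.  Variables with an all-zero bias
    are copied untouched.
    """
    transforms = default_transforms()
    biases = bias_fields(scenario)
    fields: dict[str, np.ndarray] = {}
    for var in VARIABLES:
        b = biases[var]
        if not np.any(b):
            fields[var] = truth.fields[var].copy()
            continue
        tr = transforms[var]
        t = tr.apply(tr.clip_physical(truth.fields[var])) + b
        fields[var] = tr.invert(t)
    model = BioclimGrid(geometry=truth.geometry, fields=fields, mask=truth.mask.copy())
    model.validate_bounds()
    return model


def sample_pollen_sites(
    truth: BioclimGrid, scheme: BiomeScheme, scenario: SyntheticScenario
) -> list[PollenSite]:
    """Sample observation sites whose labels are the biomised truth.

    With ``stratified=True`` the domain is divided into roughly square
    blocks and one random land cell drawn per block, giving the
    well-spread coverage of a real pollen-core network; otherwise cells
    are drawn uniformly without replacement.  Site coordinates are cell
    centres.
    """
    geometry = truth.geometry
    land = np.argwhere(truth.mask)
    n = scenario.n_sites
    if n > len(land):
        raise ValueError(f"n_sites={n} exceeds number of land cells ({len(land)})")
    rng = np.random.default_rng([scenario.seed, 999])

    if n == len(land):
        chosen = [tuple(rc) for rc in land]
    elif scenario.stratified:
        aspect = geometry.n_lon / geometry.n_lat
        nby = max(1, int(round(np.sqrt(n / aspect))))
        nbx = int(np.ceil(n / nby))
        row_chunks = np.array_split(np.arange(geometry.n_lat), nby)
        col_chunks = np.array_split(np.arange(geometry.n_lon), nbx)
        blocks = [(rc, cc) for rc in row_chunks for cc in col_chunks]
        order = rng.permutation(len(blocks))
        chosen: list[tuple[int, int]] = []
        taken = set()
        for bi in order:
            if len(chosen) >= n:
                break
            rows, cols = blocks[bi]
            cand = np.argwhere(truth.mask[np.ix_(rows, cols)])
            if len(cand) == 0:
                continue
            r_loc, c_loc = cand[rng.integers(len(cand))]
            cell = (int(rows[r_loc]), int(cols[c_loc]))
            if cell not in taken:
                chosen.append(cell)
                taken.add(cell)
        if len(chosen) < n:  # fill from remaining land cells
            remaining = [tuple(rc) for rc in land if tuple(rc) not in taken]
            extra = rng.choice(len(remaining), size=n - len(chosen), replace=False)
            chosen.extend(remaining[i] for i in extra)
    else:
        idx = rng.choice(len(land), size=n, replace=False)
        chosen = [tuple(land[i]) for i in idx]

    labels = biomise(truth, scheme)
    sites = []
    for k, (r, c) in enumerate(chosen):
        sites.append(
            PollenSite(
                lon=float(geometry.lons[c]),
                lat=float(geometry.lats[r]),
                observed_biome=labels.code_at(r, c),
                site_id=f"s{k:03d}",
            )
        )
    return sites
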