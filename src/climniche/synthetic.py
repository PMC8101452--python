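"""Synthetic climate grids, future ensembles, virtual species and catalogues.

Everything downstream of raw data — the PCA space, niche fits, projections
and service aggregation — is exercised against data generated here with
known ground truth. The generator emulates the structure of gridded
bioclimatic data for a tropical mountain region:

* a latent elevation field drives a temperature lapse (annual mean BIO1
  falls with elevation) and greater diurnal/seasonal amplitude at altitude;
* a latent moisture field drives the precipitation layers;
* per-cell coherence BIO5 >= BIO1 >= BIO6 holds by construction;
* futures are built from the current stack by an additive mean-temperature
  offset per (period, RCP) scenario plus a smooth GCM-specific anomaly
  field, and a multiplicative inflation of the seasonality layers (BIO4,
  BIO15);
* virtual species are sampled from known ellipsoidal niches in PC space, so
  niche fits can be checked against generating parameters.

All randomness flows from one root seed through named substreams, so each
product is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from climniche._rng import substream
from climniche.grids import (
    BIOCLIM_VARS,
    SEASONALITY_VARS,
    TEMPERATURE_LEVEL_VARS,
    BioclimStack,
    GridSpec,
    PCStack,
)

__all__ = [
    "FutureDeltaSpec",
    "TrueNiche",
    "DEFAULT_ES2_POOL",
    "generate_current_climate",
    "generate_future_ensemble",
    "generate_virtual_species",
    "generate_service_catalogue",
    "write_truth",
]

#: 19 level-2 ecosystem services in 4 level-1 categories, the standard
#: use-classification for high-Andean useful plants.
DEFAULT_ES2_POOL: tuple[tuple[str, str], ...] = (
    ("regulating", "agroforestry"),
    ("regulating", "biological control"),
    ("regulating", "erosion regulation"),
    ("regulating", "pollination"),
    ("regulating", "restoration"),
    ("regulating", "water regulation"),
    ("provisioning", "food for animals"),
    ("provisioning", "gene sources"),
    ("provisioning", "food for humans"),
    ("provisioning", "material"),
    ("provisioning", "medicinal"),
    ("supporting", "barriers/windbreakers/support"),
    ("supporting", "conservation"),
    ("supporting", "nutrient cycling"),
    ("supporting", "ornamental resources"),
    ("supporting", "soil formation"),
    ("cultural", "leisure"),
    ("cultural", "magic or religious"),
    ("cultural", "social"),
)

# Default mean warming (°C) per RCP by 2070, CMIP5-era magnitudes, and the
# fraction of that warming realized by 2050.
_RCP_WARMING_2070 = {2.6: 1.0, 4.5: 1.8, 6.0: 2.2, 8.5: 3.7}
_PERIOD_SCALE = {2050: 0.6, 2070: 1.0}
# Default seasonality inflation per RCP by 2070 (dimensionless, >= 1).
_RCP_INFLATION_2070 = {2.6: 1.02, 4.5: 1.05, 6.0: 1.08, 8.5: 1.12}


@dataclass(frozen=True)
class FutureDeltaSpec:
    """Controlled climate deltas for a factorial future-scenario ensemble.

    One stack is produced per period x RCP x GCM. ``mean_offset`` and
    ``seasonality_inflation`` map ``(period, rcp)`` to the additive
    temperature offset (°C) and the multiplicative seasonality factor
    (>= 1); when None, defaults increase with RCP severity and time horizon.
    ``gcm_noise_sd`` (°C) sets the amplitude of each GCM's smooth anomaly
    field.
    """

    periods: tuple[int, ...] = (2050, 2070)
    rcps: tuple[float, ...] = (2.6, 4.5, 6.0, 8.5)
    mean_offset: Mapping[tuple[int, float], float] | None = None
    seasonality_inflation: Mapping[tuple[int, float], float] | None = None
    n_gcms: int = 10
    gcm_noise_sd: float = 0.4

    def __post_init__(self) -> None:
        if self.n_gcms < 1:
            raise ValueError("n_gcms must be at least 1")
        if self.gcm_noise_sd < 0:
            raise ValueError("gcm_noise_sd must be nonnegative")
        for inf in (self.seasonality_inflation or {}).values():
            if inf < 1.0:
                raise ValueError("seasonality inflation factors must be >= 1")

    def offset(self, period: int, rcp: float) -> float:
        if self.mean_offset is not None:
            return float(self.mean_offset[(period, rcp)])
        return _RCP_WARMING_2070[rcp] * _PERIOD_SCALE[period]

    def inflation(self, period: int, rcp: float) -> float:
        if self.seasonality_inflation is not None:
            return float(self.seasonality_inflation[(period, rcp)])
        return 1.0 + (_RCP_INFLATION_2070[rcp] - 1.0) * _PERIOD_SCALE[period]

    @property
    def gcm_ids(self) -> tuple[str, ...]:
        return tuple(f"GCM{i + 1:02d}" for i in range(self.n_gcms))

    @property
    def scenarios(self) -> tuple[tuple[int, float], ...]:
        return tuple((p, r) for p in self.periods for r in self.rcps)


@dataclass(frozen=True)
class TrueNiche:
    """Ground-truth ellipsoidal niche of a virtual species in PC space."""

    species_id: str
    mu_true: tuple[float, ...]
    sigma_true: tuple[tuple[float, ...], ...]
    n_occurrences: int

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu_true, dtype=float)
        sigma = np.asarray(self.sigma_true, dtype=float)
        if sigma.shape != (mu.size, mu.size):
            raise ValueError("sigma_true must be k x k")
        if not np.allclose(sigma, sigma.T):
            raise ValueError("sigma_true must be symmetric")
        if np.linalg.eigvalsh(sigma)[0] <= 0:
            raise ValueError("sigma_true must be positive definite")
        if self.n_occurrences < 1:
            raise ValueError("n_occurrences must be at least 1")

    @property
    def mu(self) -> np.ndarray:
        return np.asarray(self.mu_true, dtype=float)

    @property
    def sigma(self) -> np.ndarray:
        return np.asarray(self.sigma_true, dtype=float)

    @property
    def k(self) -> int:
        return len(self.mu_true)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sd: float,
                  order: int = 3) -> np.ndarray:
    """A smooth zero-mean random field from a low-order cosine basis.

    Coefficients are always drawn (so the RNG stream advances identically
    whatever ``sd``), then the field is scaled to standard deviation ``sd``.
    """
    n_rows, n_cols = shape
    u = (np.arange(n_rows) + 0.5) / n_rows
    v = (np.arange(n_cols) + 0.5) / n_cols
    coeffs = rng.normal(size=(order + 1, order + 1))
    phases = rng.uniform(0, 2 * np.pi, size=(order + 1, order + 1, 2))
    out = np.zeros(shape)
    for i in range(order + 1):
        for j in range(order + 1):
            if i == 0 and j == 0:
                continue
            out += coeffs[i, j] * np.outer(
                np.cos(np.pi * i * u + phases[i, j, 0]),
                np.cos(np.pi * j * v + phases[i, j, 1]),
            )
    s = out.std()
    if s > 0 and sd > 0:
        out = (out - out.mean()) * (sd / s)
    else:
        out = np.zeros(shape)
    return out


def generate_current_climate(
    spec: GridSpec,
    seed: int,
    relief: float = 1.5,
    moisture_range: float = 1.0,
    noise_sd: float = 0.3,
    base_temp: float = 24.0,
    lapse_rate: float = 6.0,
    base_precip: float = 800.0,
    elevation: np.ndarray | None = None,
    moisture: np.ndarray | None = None,
) -> BioclimStack:
    """Generate a coherent 19-layer bioclim stack on the given grid.

    ``relief`` (km) scales the latent elevation field; ``lapse_rate`` (°C/km)
    sets how fast BIO1 falls with elevation; ``moisture_range`` scales the
    latent moisture gradient driving precipitation; ``noise_sd`` adds
    cell-level noise (°C for temperature layers, scaled for precipitation).
    With ``relief = moisture_range = noise_sd = 0`` every layer is spatially
    constant. ``elevation`` (km) and ``moisture`` (unitless, ~[0, 1.5])
    override the latent fields with caller-supplied grids, which makes the
    lapse relation BIO1 = base_temp - lapse_rate * elevation exact when
    ``noise_sd = 0``.

    The grid's ``nodata_fraction`` voids that fraction of cells in every
    layer consistently; generation refuses if fewer than 2 valid cells would
    remain.
    """
    shape = spec.shape
    n_cells = spec.n_cells
    n_void = int(np.floor(spec.nodata_fraction * n_cells))
    if n_cells - n_void < 2:
        raise ValueError(
            "nodata_fraction leaves fewer than 2 valid cells; refuse to generate"
        )
    rng = substream(seed, "climate")

    # latent fields in [0, 1]
    u = (np.arange(shape[0]) + 0.5) / shape[0]
    v = (np.arange(shape[1]) + 0.5) / shape[1]
    if elevation is None:
        ridge = 0.5 + 0.5 * np.outer(np.sin(np.pi * u), np.cos(np.pi * v))
        elev = np.clip(relief * (ridge + 0.15 * _smooth_field(rng, shape, 1.0)),
                       0.0, None)
    else:
        elev = np.asarray(elevation, dtype=float)
        if elev.shape != shape:
            raise ValueError("elevation field shape does not match grid")
    if moisture is None:
        moist_base = np.broadcast_to(0.5 + 0.5 * np.sin(np.pi * v), shape)
        moist = 0.5 + moisture_range * (
            moist_base - 0.5 + 0.2 * _smooth_field(rng, shape, 1.0)
        )
        moist = np.clip(moist, 0.0, 1.5)
    else:
        moist = np.asarray(moisture, dtype=float)
        if moist.shape != shape:
            raise ValueError("moisture field shape does not match grid")

    def tnoise() -> np.ndarray:
        # stream advances identically even when sd == 0
        draw = rng.normal(size=shape)
        return noise_sd * draw

    layers: dict[str, np.ndarray] = {}
    bio1 = base_temp - lapse_rate * elev + tnoise()
    warm_amp = np.clip(4.0 + 1.0 * elev + tnoise(), 0.0, None)
    cold_amp = np.clip(5.0 + 1.5 * elev + tnoise(), 0.0, None)
    layers["BIO1"] = bio1
    layers["BIO2"] = np.clip(9.0 + 1.2 * elev + tnoise(), 0.1, None)
    layers["BIO4"] = np.clip(55.0 + 20.0 * elev + 10 * tnoise(), 1.0, None)
    layers["BIO5"] = bio1 + warm_amp
    layers["BIO6"] = bio1 - cold_amp
    layers["BIO7"] = layers["BIO5"] - layers["BIO6"]
    layers["BIO3"] = np.clip(
        100.0 * layers["BIO2"] / layers["BIO7"], 1.0, 100.0
    )
    # quarter/month means stay within the [BIO6, BIO5] envelope
    layers["BIO8"] = bio1 + 0.3 * warm_amp
    layers["BIO9"] = bio1 - 0.3 * cold_amp
    layers["BIO10"] = bio1 + 0.5 * warm_amp
    layers["BIO11"] = bio1 - 0.5 * cold_amp

    pnoise_scale = 20.0 * noise_sd
    annual = np.clip(
        base_precip + 1200.0 * (moist - 0.5) + pnoise_scale * rng.normal(size=shape),
        0.0,
        None,
    )
    wet_frac = np.clip(
        0.14 + 0.04 * (moist - 0.5) + 0.002 * noise_sd * rng.normal(size=shape),
        0.02, 0.5,
    )
    dry_frac = np.clip(
        0.02 + 0.01 * (0.5 - moist) + 0.001 * noise_sd * rng.normal(size=shape),
        0.0, 0.1,
    )
    layers["BIO12"] = annual
    layers["BIO13"] = annual * wet_frac
    layers["BIO14"] = annual * dry_frac
    layers["BIO15"] = np.clip(
        40.0 + 40.0 * (0.5 - moist) + 2.0 * rng.normal(size=shape) * noise_sd,
        1.0,
        None,
    )
    layers["BIO16"] = annual * wet_frac * 2.6
    layers["BIO17"] = annual * dry_frac * 3.2
    layers["BIO18"] = annual * wet_frac * 1.6
    layers["BIO19"] = annual * dry_frac * 3.6

    mask = np.ones(shape, dtype=bool)
    if n_void:
        void = rng.choice(n_cells, size=n_void, replace=False)
        mask.flat[void] = False

    data = np.stack([layers[name] for name in BIOCLIM_VARS])
    return BioclimStack(names=BIOCLIM_VARS, data=data, mask=mask, grid=spec)


def generate_future_ensemble(
    current: BioclimStack,
    deltas: FutureDeltaSpec,
    seed: int,
) -> dict[tuple[int, float, str], BioclimStack]:
    """Build one future stack per (period, RCP, GCM).

    Temperature-level layers are shifted by the scenario's mean offset plus
    a smooth GCM- and scenario-specific anomaly field (sd ``gcm_noise_sd``);
    the seasonality layers BIO4 and BIO15 are multiplied by the scenario's
    inflation factor. Range layers (BIO2, BIO7) and precipitation totals are
    carried over unchanged, so the BIO5 >= BIO1 >= BIO6 coherence of the
    current stack is preserved. The nodata mask is inherited exactly.
    """
    out: dict[tuple[int, float, str], BioclimStack] = {}
    for period, rcp in deltas.scenarios:
        offset = deltas.offset(period, rcp)
        inflation = deltas.inflation(period, rcp)
        for gcm in deltas.gcm_ids:
            rng = substream(seed, f"gcm/{period}/{rcp:g}/{gcm}")
            anomaly = _smooth_field(rng, current.grid.shape, deltas.gcm_noise_sd)
            data = current.data.copy()
            for name in TEMPERATURE_LEVEL_VARS:
                i = current.names.index(name)
                data[i] = data[i] + offset + anomaly
            for name in SEASONALITY_VARS:
                i = current.names.index(name)
                data[i] = data[i] * inflation
            out[(period, rcp, gcm)] = BioclimStack(
                names=current.names,
                data=data,
                mask=current.mask.copy(),
                grid=current.grid,
            )
    return out


def generate_virtual_species(
    env: PCStack,
    niches: Sequence[TrueNiche],
    seed: int,
) -> pd.DataFrame:
    """Sample occurrence records for virtual species with known niches.

    For each species, cells are drawn *without replacement* — one record per
    climate cell, pre-matching the downstream dedup rule — with selection
    weight equal to the species' chi-square niche probability at the cell.
    Records carry the cell-center coordinates.

    Raises
    ------
    ValueError
        If a species' niche gives (numerically) zero weight to every valid
        cell, or asks for more occurrences than cells with positive weight.
    """
    scores = env.scores()
    if scores.shape[0] == 0:
        raise ValueError("environmental stack has no valid cells")
    rows_idx, cols_idx = env.valid_indices()
    cx, cy = env.grid.cell_centers()
    records = []
    for niche in niches:
        if niche.k != env.k:
            raise ValueError(
                f"{niche.species_id}: niche dimension {niche.k} != env k {env.k}"
            )
        rng = substream(seed, f"species/{niche.species_id}")
        diff = scores - niche.mu
        sol = np.linalg.solve(niche.sigma, diff.T)
        d2 = np.einsum("ij,ji->i", diff, sol)
        weights = stats.chi2.sf(d2, df=niche.k)
        total = weights.sum()
        n_pos = int((weights > 0).sum())
        if total <= 0 or n_pos == 0:
            raise ValueError(
                f"{niche.species_id}: all cell weights are zero — the niche "
                "has no support on this grid (center too far from the "
                "realized climate cloud)"
            )
        if niche.n_occurrences > n_pos:
            raise ValueError(
                f"{niche.species_id}: requested {niche.n_occurrences} "
                f"occurrences but only {n_pos} cells have positive weight"
            )
        chosen = rng.choice(
            scores.shape[0],
            size=niche.n_occurrences,
            replace=False,
            p=weights / total,
        )
        for c in chosen:
            records.append(
                {
                    "species": niche.species_id,
                    "decimalLongitude": cx[rows_idx[c], cols_idx[c]],
                    "decimalLatitude": cy[rows_idx[c], cols_idx[c]],
                    "elevation": np.nan,
                    "source": "synthetic",
                }
            )
    return pd.DataFrame(
        records,
        columns=["species", "decimalLongitude", "decimalLatitude", "elevation", "source"],
    )


def generate_service_catalogue(
    species_ids: Sequence[str],
    es2_pool: Sequence[tuple[str, str]] = DEFAULT_ES2_POOL,
    services_per_species: tuple[int, int] = (1, 3),
    seed: int = 0,
) -> pd.DataFrame:
    """Assign each species a random set of distinct level-2 services.

    The number of services per species is uniform on the inclusive range
    ``services_per_species`` (default 1..3, giving a median of two services
    per species over many species). Every ES2 label carries its ES1 parent;
    the output schema matches the catalogue reader
    (species, use, es_level1, es_level2).
    """
    if not es2_pool:
        raise ValueError("es2_pool must be non-empty")
    lo, hi = services_per_species
    if lo < 1 or hi < lo:
        raise ValueError("services_per_species must satisfy 1 <= min <= max")
    if hi > len(es2_pool):
        raise ValueError(
            f"services_per_species max {hi} exceeds pool size {len(es2_pool)}"
        )
    rng = substream(seed, "catalogue")
    pool = list(es2_pool)
    rows = []
    for sp in species_ids:
        m = int(rng.integers(lo, hi + 1))
        picks = rng.choice(len(pool), size=m, replace=False)
        for p in sorted(picks):
            es1, es2 = pool[p]
            rows.append(
                {
                    "species": sp,
                    "use": f"use: {es2}",
                    "es_level1": es1,
                    "es_level2": es2,
                }
            )
    return pd.DataFrame(rows, columns=["species", "use", "es_level1", "es_level2"])


def write_truth(niches: Sequence[TrueNiche], path: str | Path) -> Path:
    """Write ground-truth niche parameters as CSV (sigma row-major)."""
    path = Path(path)
    rows = []
    for n in niches:
        row: dict = {"species": n.species_id, "n_occurrences": n.n_occurrences}
        for i, m in enumerate(n.mu):
            row[f"mu_{i + 1}"] = m
        for i in range(n.k):
            for j in range(n.k):
                row[f"sigma_{i + 1}_{j + 1}"] = n.sigma[i, j]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
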