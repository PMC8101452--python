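"""Geographic projection of niches and bootstrap area accounting.

A fitted niche is mapped onto a climate grid as a potential-niche
probability surface: each cell gets the within-niche probability of its PC
score. Potential-niche *area* is the probability-weighted area, the sum of
cell probabilities times the per-cell area — a soft area that needs no
threshold. For futures, each bootstrap model is paired with its own current
area, and for every (period, RCP) scenario one GCM is drawn uniformly at
random per bootstrap, propagating both sampling and climate-model
uncertainty into the area distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from climniche._rng import substream
from climniche.grids import PCStack
from climniche.niche import BootstrapEnsemble, NicheModel, niche_probability

__all__ = [
    "NicheMap",
    "project_niche",
    "niche_area",
    "scenario_label",
    "scenario_area_table",
    "mean_niche_map",
]

CURRENT = "current"


def scenario_label(period: int, rcp: float) -> str:
    return f"{period}_rcp{rcp:g}"


@dataclass
class NicheMap:
    """Potential-niche probability surface with provenance."""

    probs: np.ndarray
    mask: np.ndarray
    grid: "object"
    species: str | None = None
    bootstrap_id: int | str | None = None
    scenario: str = CURRENT
    gcm_id: str | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        valid = self.probs[self.mask]
        if valid.size and (np.nanmin(valid) < 0 or np.nanmax(valid) > 1):
            raise ValueError("probabilities must lie in [0, 1] at valid cells")


def project_niche(
    model: NicheModel,
    env: PCStack,
    species: str | None = None,
    scenario: str = CURRENT,
    gcm_id: str | None = None,
) -> NicheMap:
    """Map a niche model over a PC-score grid.

    Each valid cell receives ``niche_probability(model, score)``; nodata
    cells stay NaN.
    """
    if env.k != model.df:
        raise ValueError(
            f"environmental space has k={env.k} but model df={model.df}"
        )
    probs = np.full(env.grid.shape, np.nan)
    scores = env.scores()
    if scores.shape[0]:
        probs[env.mask] = niche_probability(model, scores)
    return NicheMap(
        probs=probs,
        mask=env.mask,
        grid=env.grid,
        species=species,
        bootstrap_id=model.bootstrap_id,
        scenario=scenario,
        gcm_id=gcm_id,
    )


def niche_area(niche_map: NicheMap, cell_area: float | None = None) -> float:
    """Potential-niche area: sum of valid-cell probabilities x cell area (km²)."""
    if cell_area is None:
        cell_area = niche_map.grid.cell_area
    vals = niche_map.probs[niche_map.mask]
    return float(np.nansum(vals) * cell_area)


def _area_from_scores(
    model: NicheModel, scores: np.ndarray, cell_area: float
) -> float:
    if scores.shape[0] == 0:
        return 0.0
    return float(niche_probability(model, scores).sum() * cell_area)


def scenario_area_table(
    ensemble: BootstrapEnsemble,
    current_env: PCStack,
    future_envs: dict[tuple[int, float, str], PCStack],
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bootstrap potential-niche areas for current and future scenarios.

    For every bootstrap model the current area is computed, then for each
    (period, RCP) scenario one GCM is drawn uniformly at random (an
    independent draw per species x bootstrap x scenario) and the future area
    computed with the *same* model — a paired design, so per-bootstrap
    changes are meaningful. Returns the long area table
    (species, bootstrap_id, scenario, period, rcp, gcm_id, area) and the
    GCM-draw log.

    Raises
    ------
    ValueError
        If some (period, RCP) scenario has no GCM stack.
    """
    if not future_envs:
        raise ValueError("no future scenarios provided (zero GCM stacks)")
    scenarios: dict[tuple[int, float], list[str]] = {}
    for (period, rcp, gcm) in future_envs:
        scenarios.setdefault((period, rcp), []).append(gcm)
    for key, gcms in scenarios.items():
        if not gcms:
            raise ValueError(f"scenario {key} has no GCM stacks")
    scenario_keys = sorted(scenarios)
    for gcms in scenarios.values():
        gcms.sort()

    rng = substream(seed, f"gcm-draws/{ensemble.species_id}")
    cell_area = current_env.grid.cell_area
    # extract valid-cell score tables once; the per-model loop only solves
    current_scores = current_env.scores()
    future_scores = {key: env.scores() for key, env in future_envs.items()}
    rows = []
    draw_log = []
    for model in ensemble.models:
        area_now = _area_from_scores(model, current_scores, cell_area)
        rows.append(
            {
                "species": ensemble.species_id,
                "bootstrap_id": model.bootstrap_id,
                "scenario": CURRENT,
                "period": pd.NA,
                "rcp": np.nan,
                "gcm_id": pd.NA,
                "area": area_now,
            }
        )
        for (period, rcp) in scenario_keys:
            gcms = scenarios[(period, rcp)]
            gcm = gcms[int(rng.integers(0, len(gcms)))]
            area_fut = _area_from_scores(
                model, future_scores[(period, rcp, gcm)], cell_area
            )
            rows.append(
                {
                    "species": ensemble.species_id,
                    "bootstrap_id": model.bootstrap_id,
                    "scenario": scenario_label(period, rcp),
                    "period": period,
                    "rcp": rcp,
                    "gcm_id": gcm,
                    "area": area_fut,
                }
            )
            draw_log.append(
                {
                    "species": ensemble.species_id,
                    "bootstrap_id": model.bootstrap_id,
                    "scenario": scenario_label(period, rcp),
                    "gcm_id": gcm,
                }
            )
    areas = pd.DataFrame(
        rows,
        columns=["species", "bootstrap_id", "scenario", "period", "rcp",
                 "gcm_id", "area"],
    )
    log = pd.DataFrame(
        draw_log, columns=["species", "bootstrap_id", "scenario", "gcm_id"]
    )
    return areas, log


def mean_niche_map(
    ensemble: BootstrapEnsemble,
    env: PCStack,
    scenario: str = CURRENT,
    gcm_id: str | None = None,
) -> NicheMap:
    """Bootstrap-mean probability surface (figure export, not area stats)."""
    probs = np.full(env.grid.shape, np.nan)
    scores = env.scores()
    if scores.shape[0]:
        acc = np.zeros(scores.shape[0])
        for model in ensemble.models:
            acc += niche_probability(model, scores)
        probs[env.mask] = acc / ensemble.B
    return NicheMap(
        probs=probs,
        mask=env.mask,
        grid=env.grid,
        species=ensemble.species_id,
        bootstrap_id="bootstrap-mean",
        scenario=scenario,
        gcm_id=gcm_id,
    )
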