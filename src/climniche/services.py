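"""Species-to-ecosystem-service mapping and pooled change distributions.

Each species carries one or more level-2 ecosystem services (ES2), each
nested under one of four level-1 categories (ES1: cultural, provisioning,
regulating, supporting). Potential-niche areas are first converted to
percentages of the study area; per species and bootstrap the change under a
scenario is the future percentage minus the paired current percentage, in
percentage points (pp). Per service the change distribution pools these
values over all member species and bootstraps — a species contributes once
per ES2 it provides, so at level 1 the pooled n counts species-service
memberships, not distinct species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from climniche.projection import CURRENT

__all__ = [
    "ServiceCatalogue",
    "ChangeDistribution",
    "read_catalogue",
    "area_percentages",
    "change_distributions",
    "summarize_changes",
    "changes_to_frame",
]

logger = logging.getLogger(__name__)

_CATALOGUE_COLUMNS = ("species", "use", "es_level1", "es_level2")


@dataclass
class ServiceCatalogue:
    """Normalized species → use → (ES1, ES2) table.

    ``table`` holds unique (species, es_level2) memberships after label
    normalization; ``n_collapsed`` counts duplicate memberships merged by
    the reader.
    """

    table: pd.DataFrame
    n_collapsed: int = 0

    @property
    def species(self) -> list[str]:
        return sorted(self.table["species"].unique())

    def memberships(self, level: int) -> pd.DataFrame:
        """(species, service) membership rows at ES level 1 or 2.

        At level 1 a species appears once per member ES2 (membership
        weighting), so the same species can contribute several times to one
        ES1 category.
        """
        if level == 2:
            out = self.table[["species", "es_level1", "es_level2"]].copy()
            out["service"] = out["es_level2"]
        elif level == 1:
            out = self.table[["species", "es_level1", "es_level2"]].copy()
            out["service"] = out["es_level1"]
        else:
            raise ValueError("level must be 1 or 2")
        return out

    def services_per_species(self) -> pd.Series:
        return self.table.groupby("species")["es_level2"].nunique()


def _normalize(s: pd.Series) -> pd.Series:
    return s.astype(str).str.strip().str.replace(r"\s+", " ", regex=True).str.lower()


def read_catalogue(path: str | Path | pd.DataFrame) -> ServiceCatalogue:
    """Read and normalize a species→use→service catalogue CSV.

    Labels are case/whitespace-normalized; duplicate (species, ES2) rows are
    collapsed with a count report. Refuses if any ES2 label maps to two
    different ES1 parents, naming the conflict.
    """
    raw = path.copy() if isinstance(path, pd.DataFrame) else pd.read_csv(path)
    missing = [c for c in _CATALOGUE_COLUMNS if c not in raw.columns and c != "use"]
    if missing:
        raise ValueError(f"catalogue is missing column(s): {missing}")
    table = pd.DataFrame(
        {
            "species": raw["species"].astype(str).str.strip(),
            "use": raw["use"].astype(str).str.strip() if "use" in raw.columns else "",
            "es_level1": _normalize(raw["es_level1"]),
            "es_level2": _normalize(raw["es_level2"]),
        }
    )
    parents = table.groupby("es_level2")["es_level1"].nunique()
    conflicts = parents[parents > 1].index.tolist()
    if conflicts:
        raise ValueError(
            f"es_level2 label(s) mapped to multiple es_level1 parents: {conflicts}"
        )
    before = len(table)
    table = table.drop_duplicates(subset=["species", "es_level2"]).reset_index(
        drop=True
    )
    n_collapsed = before - len(table)
    if n_collapsed:
        logger.info("collapsed %d duplicate (species, ES2) rows", n_collapsed)
    return ServiceCatalogue(table=table, n_collapsed=n_collapsed)


def area_percentages(areas: pd.DataFrame, study_area: float) -> pd.DataFrame:
    """Add ``pct`` = 100 x area / study_area (km²) to an area table."""
    if study_area <= 0:
        raise ValueError("study_area must be positive")
    out = areas.copy()
    out["pct"] = 100.0 * out["area"] / study_area
    return out


@dataclass
class ChangeDistribution:
    """Pooled percentage-point changes for one service x scenario."""

    es_level: int
    es_name: str
    scenario: str
    values: np.ndarray
    n_species: int
    per_species: pd.DataFrame  # (species, bootstrap_id, delta_pp)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n(self) -> int:
        """Species-service membership count feeding this bean."""
        return self.n_species


def change_distributions(
    areas: pd.DataFrame,
    catalogue: ServiceCatalogue,
    level: int = 2,
) -> list[ChangeDistribution]:
    """Pool per-bootstrap area changes by ecosystem service.

    ``areas`` must carry ``pct`` (see :func:`area_percentages`) with one
    ``current`` row and one row per future scenario for every
    (species, bootstrap). The change is pct_future - pct_current, paired
    within a bootstrap. Species absent from the catalogue are reported and
    skipped; a scenario missing for some species is an error (ragged
    pooling would bias the distributions).
    """
    if "pct" not in areas.columns:
        raise ValueError("areas must have a 'pct' column; run area_percentages first")
    species_in_areas = sorted(areas["species"].unique())
    members = catalogue.memberships(level)
    known = set(members["species"])
    skipped = [sp for sp in species_in_areas if sp not in known]
    if skipped:
        logger.warning(
            "species without catalogue entry skipped from pooling: %s",
            ", ".join(skipped),
        )
    used = [sp for sp in species_in_areas if sp in known]

    current = areas[areas["scenario"] == CURRENT].set_index(
        ["species", "bootstrap_id"]
    )["pct"]
    future = areas[areas["scenario"] != CURRENT]
    scenario_names = sorted(future["scenario"].unique())

    # paired deltas per (species, bootstrap, scenario)
    deltas: dict[str, dict[str, pd.DataFrame]] = {}
    for sp in used:
        fut_sp = future[future["species"] == sp]
        got = set(fut_sp["scenario"].unique())
        missing = [s for s in scenario_names if s not in got]
        if missing:
            raise ValueError(
                f"species {sp} lacks scenario(s) {missing}: refusing ragged pooling"
            )
        cur_sp = current.loc[sp]
        per_scen: dict[str, pd.DataFrame] = {}
        for scen, grp in fut_sp.groupby("scenario"):
            d = grp[["bootstrap_id", "pct"]].copy()
            d["delta_pp"] = d["pct"].to_numpy() - cur_sp.loc[
                d["bootstrap_id"]
            ].to_numpy()
            per_scen[str(scen)] = d[["bootstrap_id", "delta_pp"]]
        deltas[sp] = per_scen

    out: list[ChangeDistribution] = []
    member_rows = members[members["species"].isin(used)]
    for service, grp in member_rows.groupby("service", sort=True):
        for scen in scenario_names:
            parts = []
            for _, mrow in grp.iterrows():
                sp = mrow["species"]
                d = deltas[sp][scen].copy()
                d.insert(0, "species", sp)
                parts.append(d)
            pooled = pd.concat(parts, ignore_index=True)
            out.append(
                ChangeDistribution(
                    es_level=level,
                    es_name=str(service),
                    scenario=scen,
                    values=pooled["delta_pp"].to_numpy(),
                    n_species=len(grp),
                    per_species=pooled,
                )
            )
    return out


def changes_to_frame(distributions: list[ChangeDistribution]) -> pd.DataFrame:
    """Long export of pooled values (one row per contributing value)."""
    frames = []
    for dist in distributions:
        d = dist.per_species.copy()
        d.insert(0, "scenario", dist.scenario)
        d.insert(0, "es_name", dist.es_name)
        d.insert(0, "es_level", dist.es_level)
        frames.append(d)
    if not frames:
        return pd.DataFrame(
            columns=["es_level", "es_name", "scenario", "species",
                     "bootstrap_id", "delta_pp"]
        )
    return pd.concat(frames, ignore_index=True)


def summarize_changes(distributions: list[ChangeDistribution]) -> pd.DataFrame:
    """Quantile summary (2.5/25/50/75/97.5%) per service x scenario."""
    rows = []
    for dist in distributions:
        q = np.percentile(dist.values, [2.5, 25, 50, 75, 97.5])
        rows.append(
            {
                "es_level": dist.es_level,
                "es_name": dist.es_name,
                "scenario": dist.scenario,
                "n_memberships": dist.n_species,
                "n_values": dist.values.size,
                "q2.5": q[0],
                "q25": q[1],
                "median": q[2],
                "q75": q[3],
                "q97.5": q[4],
            }
        )
    return pd.DataFrame(rows)
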