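"""Occurrence reading, cleaning and per-cell deduplication.

Records arrive as Darwin-Core-style CSV rows (species, decimalLongitude,
decimalLatitude, optional elevation). Cleaning applies, in order: a
coordinate bounds filter, removal of records falling on nodata cells, an
optional elevation cross-check against a DEM (records whose label elevation
disagrees with the DEM by more than a tolerance are flagged, and optionally
dropped), and deduplication to one record per species per climate cell —
the first record by input order survives. Every rule reports how many
records it removed, per species, so the audit trail is complete.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from climniche.grids import PCStack, RasterStack

__all__ = [
    "OccurrenceTable",
    "CleanOccurrences",
    "read_occurrences",
    "clean_occurrences",
    "apply_min_records",
    "DEFAULT_COLUMN_ALIASES",
]

logger = logging.getLogger(__name__)

#: Accepted column-name aliases for each canonical field, tried in order.
DEFAULT_COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "species": ("species", "scientificName", "scientific_name", "taxon"),
    "decimalLongitude": ("decimalLongitude", "longitude", "lon", "x"),
    "decimalLatitude": ("decimalLatitude", "latitude", "lat", "y"),
    "elevation": ("elevation", "elev", "altitude", "verbatimElevation"),
    "source": ("source", "institutionCode", "dataset"),
}

_REQUIRED = ("species", "decimalLongitude", "decimalLatitude")
_RULES = ("out_of_bounds", "nodata_cell", "elevation_mismatch", "duplicate_cell")


@dataclass
class OccurrenceTable:
    """Typed occurrence records plus a count of malformed input rows."""

    records: pd.DataFrame
    n_malformed: int = 0

    def __len__(self) -> int:
        return len(self.records)

    @property
    def species(self) -> list[str]:
        return list(dict.fromkeys(self.records["species"]))


def read_occurrences(
    path: str | Path | pd.DataFrame,
    aliases: dict[str, tuple[str, ...]] | None = None,
) -> OccurrenceTable:
    """Read an occurrence CSV, resolving Darwin-Core column aliases.

    Rows with a missing species or non-numeric coordinates are excluded and
    counted as malformed (logged, never silently dropped). Raises if a
    required column is absent under every alias, naming it.
    """
    aliases = aliases or DEFAULT_COLUMN_ALIASES
    if isinstance(path, pd.DataFrame):
        raw = path.copy()
    else:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    colmap: dict[str, str] = {}
    for canonical, options in aliases.items():
        for opt in options:
            if opt in raw.columns:
                colmap[canonical] = opt
                break
    for req in _REQUIRED:
        if req not in colmap:
            raise ValueError(
                f"required column {req!r} not found "
                f"(accepted aliases: {aliases[req]})"
            )
    out = pd.DataFrame()
    out["species"] = raw[colmap["species"]].astype(str).str.strip()
    out["decimalLongitude"] = pd.to_numeric(
        raw[colmap["decimalLongitude"]], errors="coerce"
    )
    out["decimalLatitude"] = pd.to_numeric(
        raw[colmap["decimalLatitude"]], errors="coerce"
    )
    if "elevation" in colmap:
        out["elevation"] = pd.to_numeric(raw[colmap["elevation"]], errors="coerce")
    else:
        out["elevation"] = np.nan
    out["source"] = raw[colmap["source"]] if "source" in colmap else ""
    ok = (
        (out["species"] != "")
        & np.isfinite(out["decimalLongitude"])
        & np.isfinite(out["decimalLatitude"])
    )
    n_malformed = int((~ok).sum())
    if n_malformed:
        logger.warning("excluded %d malformed occurrence rows", n_malformed)
    return OccurrenceTable(
        records=out[ok].reset_index(drop=True), n_malformed=n_malformed
    )


@dataclass
class CleanOccurrences:
    """Per-species cell sets in PC space plus the cleaning audit report.

    ``per_species`` maps species to a frame with columns
    (cell_row, cell_col, PC1..PCk); within a species cell indices are
    unique and every row maps to a valid (non-nodata) climate cell.
    ``report`` is long-form (species, rule, n_removed); ``flags`` lists
    elevation mismatches that were flagged but retained.
    """

    per_species: dict[str, pd.DataFrame]
    report: pd.DataFrame
    flags: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["species", "decimalLongitude", "decimalLatitude",
                     "elevation", "dem_elevation"]
        )
    )
    excluded: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["species", "n_cells"])
    )

    @property
    def species(self) -> list[str]:
        return list(self.per_species)

    def counts(self) -> dict[str, int]:
        return {sp: len(df) for sp, df in self.per_species.items()}

    def points(self, species: str) -> np.ndarray:
        """PC-score matrix (n_cells, k) for one species."""
        df = self.per_species[species]
        pc_cols = [c for c in df.columns if c.startswith("PC")]
        return df[pc_cols].to_numpy(dtype=float)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for sp, df in self.per_species.items():
            d = df.copy()
            d.insert(0, "species", sp)
            frames.append(d)
        if not frames:
            return pd.DataFrame(columns=["species", "cell_row", "cell_col"])
        return pd.concat(frames, ignore_index=True)


def _empty_report(species: list[str]) -> pd.DataFrame:
    rows = [
        {"species": sp, "rule": rule, "n_removed": 0}
        for sp in species
        for rule in _RULES
    ]
    return pd.DataFrame(rows, columns=["species", "rule", "n_removed"])


def clean_occurrences(
    occ: OccurrenceTable | pd.DataFrame,
    env: PCStack,
    bounds: tuple[float, float, float, float] | None = None,
    dem: RasterStack | np.ndarray | None = None,
    max_elev_diff: float = 500.0,
    drop_on_elevation_flag: bool = False,
) -> CleanOccurrences:
    """Filter, cross-check and deduplicate occurrences onto climate cells.

    Rules are applied in order: (1) ``bounds`` box filter
    (x_min, y_min, x_max, y_max), with records outside the grid extent also
    removed under this rule; (2) records on nodata cells dropped;
    (3) with a ``dem``, records whose label elevation differs from the DEM
    by more than ``max_elev_diff`` m are flagged — and dropped only when
    ``drop_on_elevation_flag`` is set; records lacking a label elevation are
    never touched by this rule; (4) one record per species per climate
    cell, first by input order. A species filtered down to nothing stays in
    the output with an empty set and a logged warning.
    """
    records = occ.records if isinstance(occ, OccurrenceTable) else occ
    species_order = list(dict.fromkeys(records["species"]))
    report = _empty_report(species_order)

    def count(sp: str, rule: str, n: int) -> None:
        report.loc[
            (report["species"] == sp) & (report["rule"] == rule), "n_removed"
        ] += n

    if dem is not None and not isinstance(dem, np.ndarray):
        dem = dem.data[0]

    per_species: dict[str, pd.DataFrame] = {}
    flag_rows = []
    k = env.k
    pc_cols = [f"PC{i + 1}" for i in range(k)]
    for sp in species_order:
        df = records[records["species"] == sp].reset_index(drop=True)
        x = df["decimalLongitude"].to_numpy(dtype=float)
        y = df["decimalLatitude"].to_numpy(dtype=float)
        row, col, inside = env.grid.locate(x, y)
        keep = inside.copy()
        if bounds is not None:
            x_min, y_min, x_max, y_max = bounds
            keep &= (x >= x_min) & (x <= x_max) & (y >= y_min) & (y <= y_max)
        count(sp, "out_of_bounds", int((~keep).sum()))

        valid_cell = np.zeros(len(df), dtype=bool)
        valid_cell[keep] = env.mask[row[keep], col[keep]]
        count(sp, "nodata_cell", int((keep & ~valid_cell).sum()))
        keep &= valid_cell

        if dem is not None:
            label_elev = df["elevation"].to_numpy(dtype=float)
            has_label = np.isfinite(label_elev)
            dem_elev = np.full(len(df), np.nan)
            dem_elev[keep] = dem[row[keep], col[keep]]
            mismatch = keep & has_label & (
                np.abs(dem_elev - label_elev) > max_elev_diff
            )
            for i in np.nonzero(mismatch)[0]:
                flag_rows.append(
                    {
                        "species": sp,
                        "decimalLongitude": x[i],
                        "decimalLatitude": y[i],
                        "elevation": label_elev[i],
                        "dem_elevation": dem_elev[i],
                    }
                )
            if drop_on_elevation_flag:
                count(sp, "elevation_mismatch", int(mismatch.sum()))
                keep &= ~mismatch

        idx = np.nonzero(keep)[0]
        cells = list(zip(row[idx], col[idx]))
        seen: set[tuple[int, int]] = set()
        survivors = []
        for i, cell in zip(idx, cells):
            if cell in seen:
                continue
            seen.add(cell)
            survivors.append((i, cell))
        count(sp, "duplicate_cell", len(idx) - len(survivors))

        rows_out = []
        for i, (r, c) in survivors:
            entry = {"cell_row": int(r), "cell_col": int(c)}
            for j, pc in enumerate(pc_cols):
                entry[pc] = env.data[j, r, c]
            rows_out.append(entry)
        per_species[sp] = pd.DataFrame(
            rows_out, columns=["cell_row", "cell_col", *pc_cols]
        )
        if not rows_out:
            logger.warning("species %s: all records removed by cleaning", sp)

    flags = pd.DataFrame(
        flag_rows,
        columns=["species", "decimalLongitude", "decimalLatitude",
                 "elevation", "dem_elevation"],
    )
    return CleanOccurrences(per_species=per_species, report=report, flags=flags)


def apply_min_records(
    clean: CleanOccurrences, min_n: int = 20
) -> CleanOccurrences:
    """Exclude species with fewer than ``min_n`` retained climate cells.

    Returns a new CleanOccurrences whose ``excluded`` frame lists the
    dropped species and their cell counts. The default of 20 records is the
    conventional minimum for fitting a 3-D covariance with some stability.
    """
    if min_n < 0:
        raise ValueError("min_n must be nonnegative")
    kept = {sp: df for sp, df in clean.per_species.items() if len(df) >= min_n}
    excluded = pd.DataFrame(
        [
            {"species": sp, "n_cells": len(df)}
            for sp, df in clean.per_species.items()
            if len(df) < min_n
        ],
        columns=["species", "n_cells"],
    )
    if len(excluded):
        logger.info(
            "excluded %d species below min_n=%d: %s",
            len(excluded),
            min_n,
            ", ".join(excluded["species"]),
        )
    return CleanOccurrences(
        per_species=kept,
        report=clean.report.copy(),
        flags=clean.flags.copy(),
        excluded=excluded,
    )
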