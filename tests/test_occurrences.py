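"""Occurrence parsing, cleaning rules and the audit-trail invariants."""

import io

import numpy as np
import pandas as pd
import pytest

from climniche.grids import GridSpec, PCStack
from climniche.occurrences import (
    apply_min_records,
    clean_occurrences,
    read_occurrences,
)


@pytest.fixture()
def tiny_env():
    """3x3 single-PC grid with one nodata cell at (1, 1)."""
    data = np.arange(9, dtype=float).reshape(1, 3, 3)
    mask = np.ones((3, 3), bool)
    mask[1, 1] = False
    return PCStack(names=("PC1",), data=data, mask=mask, grid=GridSpec(3, 3))


def _centers(env, cells):
    cx, cy = env.grid.cell_centers()
    return [(cx[r, c], cy[r, c]) for r, c in cells]


class TestRead:
    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "o.csv"
        p.write_text("species,decimalLongitude,decimalLatitude\n")
        table = read_occurrences(p)
        assert len(table) == 0
        assert table.n_malformed == 0

    def test_malformed_rows_counted_not_silently_dropped(self, tmp_path):
        p = tmp_path / "o.csv"
        p.write_text(
            "species,decimalLongitude,decimalLatitude\n"
            "a,1.0,2.0\n"
            "a,1.0,not-a-number\n"
            ",1.0,2.0\n"
        )
        table = read_occurrences(p)
        assert len(table) == 1
        assert table.n_malformed == 2

    def test_parse_fidelity_and_aliases(self, tmp_path):
        p = tmp_path / "o.csv"
        p.write_text(
            "scientificName,lon,lat,elev\n"
            "Espeletia sp.,0.5,1.5,3100\n"
            "Puya sp.,1.5,2.5,2800\n"
            "Puya sp.,2.5,0.5,\n"
        )
        table = read_occurrences(p)
        assert len(table) == 3
        rec = table.records.iloc[0]
        assert rec["species"] == "Espeletia sp."
        assert rec["decimalLongitude"] == 0.5
        assert rec["elevation"] == 3100
        assert np.isnan(table.records.iloc[2]["elevation"])

    def test_missing_required_column_named(self, tmp_path):
        p = tmp_path / "o.csv"
        p.write_text("species,decimalLongitude\nx,1\n")
        with pytest.raises(ValueError, match="decimalLatitude"):
            read_occurrences(p)


class TestClean:
    def test_toy_five_records_retains_three(self, tiny_env):
        # two records share cell (0,0); one falls on the nodata cell (1,1);
        # two land on distinct valid cells
        pts = _centers(tiny_env, [(0, 0), (0, 0), (1, 1), (2, 2), (0, 2)])
        df = pd.DataFrame(
            {
                "species": ["s"] * 5,
                "decimalLongitude": [p[0] for p in pts],
                "decimalLatitude": [p[1] for p in pts],
                "elevation": np.nan,
            }
        )
        clean = clean_occurrences(df, tiny_env)
        assert len(clean.per_species["s"]) == 3
        rep = clean.report.set_index("rule")["n_removed"]
        assert rep["nodata_cell"] == 1
        assert rep["duplicate_cell"] == 1
        assert rep["out_of_bounds"] == 0

    def test_empty_input_empty_output(self, tiny_env):
        df = pd.DataFrame(
            columns=["species", "decimalLongitude", "decimalLatitude", "elevation"]
        )
        clean = clean_occurrences(df, tiny_env)
        assert clean.per_species == {}
        assert (clean.report["n_removed"] == 0).all() if len(clean.report) else True

    def test_all_distinct_valid_cells_is_a_noop(self, tiny_env):
        pts = _centers(tiny_env, [(0, 0), (0, 1), (2, 2)])
        df = pd.DataFrame(
            {
                "species": ["s"] * 3,
                "decimalLongitude": [p[0] for p in pts],
                "decimalLatitude": [p[1] for p in pts],
                "elevation": np.nan,
            }
        )
        clean = clean_occurrences(df, tiny_env)
        assert len(clean.per_species["s"]) == 3
        assert (clean.report["n_removed"] == 0).all()

    def test_retained_rows_carry_pc_scores(self, tiny_env):
        pts = _centers(tiny_env, [(2, 1)])
        df = pd.DataFrame(
            {
                "species": ["s"],
                "decimalLongitude": [pts[0][0]],
                "decimalLatitude": [pts[0][1]],
                "elevation": np.nan,
            }
        )
        clean = clean_occurrences(df, tiny_env)
        row = clean.per_species["s"].iloc[0]
        assert (row["cell_row"], row["cell_col"]) == (2, 1)
        assert row["PC1"] == tiny_env.data[0, 2, 1]

    def test_first_duplicate_survives(self, tiny_env):
        # both records map to cell (0,0); the first input row wins
        cx, cy = tiny_env.grid.cell_centers()
        df = pd.DataFrame(
            {
                "species": ["s", "s"],
                "decimalLongitude": [cx[0, 0] - 0.2, cx[0, 0] + 0.2],
                "decimalLatitude": [cy[0, 0], cy[0, 0]],
                "elevation": np.nan,
            }
        )
        clean = clean_occurrences(df, tiny_env)
        assert len(clean.per_species["s"]) == 1

    def test_bounds_filter_and_outside_grid(self, tiny_env):
        pts = _centers(tiny_env, [(0, 0), (2, 2)])
        df = pd.DataFrame(
            {
                "species": ["s"] * 3,
                "decimalLongitude": [pts[0][0], pts[1][0], 99.0],
                "decimalLatitude": [pts[0][1], pts[1][1], 99.0],
                "elevation": np.nan,
            }
        )
        clean = clean_occurrences(df, tiny_env, bounds=(0.0, -1.0, 3.0, 0.0))
        rep = clean.report.set_index("rule")["n_removed"]
        # (99, 99) is outside the grid; (2,2)'s center y=-2.5 is below the
        # bounds box y_min=-1; only (0,0) at y=-0.5 survives
        assert rep["out_of_bounds"] == 2
        assert len(clean.per_species["s"]) == 1

    def test_elevation_flag_versus_drop(self, tiny_env):
        dem = np.full((3, 3), 3000.0)
        pts = _centers(tiny_env, [(0, 0), (0, 1), (0, 2)])
        df = pd.DataFrame(
            {
                "species": ["s"] * 3,
                "decimalLongitude": [p[0] for p in pts],
                "decimalLatitude": [p[1] for p in pts],
                "elevation": [3100.0, 800.0, np.nan],  # second is >500 m off
            }
        )
        flagged = clean_occurrences(df, tiny_env, dem=dem, max_elev_diff=500)
        assert len(flagged.per_species["s"]) == 3  # flag-only by default
        assert len(flagged.flags) == 1
        dropped = clean_occurrences(
            df, tiny_env, dem=dem, max_elev_diff=500, drop_on_elevation_flag=True
        )
        assert len(dropped.per_species["s"]) == 2
        rep = dropped.report.set_index("rule")["n_removed"]
        assert rep["elevation_mismatch"] == 1
        # records without a label elevation are never dropped by this rule
        assert (0, 2) in {
            (r.cell_row, r.cell_col)
            for r in dropped.per_species["s"].itertuples()
        }

    def test_cleaning_is_idempotent_and_conserves_counts(self, tiny_env):
        rng = np.random.default_rng(6)
        n = 40
        df = pd.DataFrame(
            {
                "species": rng.choice(["a", "b"], size=n),
                "decimalLongitude": rng.uniform(-0.5, 3.5, size=n),
                "decimalLatitude": rng.uniform(-3.5, 0.5, size=n),
                "elevation": np.nan,
            }
        )
        clean = clean_occurrences(df, tiny_env)
        for sp in clean.per_species:
            removed = clean.report.loc[
                clean.report["species"] == sp, "n_removed"
            ].sum()
            assert len(clean.per_species[sp]) + removed == (df["species"] == sp).sum()
        # re-clean the cleaned records: nothing changes
        cx, cy = tiny_env.grid.cell_centers()
        frames = []
        for sp, d in clean.per_species.items():
            frames.append(
                pd.DataFrame(
                    {
                        "species": sp,
                        "decimalLongitude": cx[d["cell_row"], d["cell_col"]],
                        "decimalLatitude": cy[d["cell_row"], d["cell_col"]],
                        "elevation": np.nan,
                    }
                )
            )
        again = clean_occurrences(pd.concat(frames, ignore_index=True), tiny_env)
        assert (again.report["n_removed"] == 0).all()
        for sp in clean.per_species:
            assert set(
                map(tuple, again.per_species[sp][["cell_row", "cell_col"]].values)
            ) == set(map(tuple, clean.per_species[sp][["cell_row", "cell_col"]].values))


class TestMinRecords:
    def _clean_with_counts(self, tiny_env, counts):
        per_species = {}
        for sp, n in counts.items():
            per_species[sp] = pd.DataFrame(
                {"cell_row": range(n), "cell_col": [0] * n, "PC1": [0.0] * n}
            )
        from climniche.occurrences import CleanOccurrences, _empty_report

        return CleanOccurrences(
            per_species=per_species, report=_empty_report(list(counts))
        )

    def test_threshold_edge_nineteen_is_excluded_at_twenty(self, tiny_env):
        clean = self._clean_with_counts(tiny_env, {"rich": 25, "sparse": 19})
        out = apply_min_records(clean, min_n=20)
        assert list(out.per_species) == ["rich"]
        assert out.excluded.iloc[0]["species"] == "sparse"
        assert out.excluded.iloc[0]["n_cells"] == 19

    def test_min_n_zero_excludes_nothing(self, tiny_env):
        clean = self._clean_with_counts(tiny_env, {"a": 1, "b": 0})
        out = apply_min_records(clean, min_n=0)
        assert set(out.per_species) == {"a", "b"}
        assert len(out.excluded) == 0

    def test_default_threshold_is_twenty(self, tiny_env):
        import inspect

        sig = inspect.signature(apply_min_records)
        assert sig.parameters["min_n"].default == 20
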