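"""Generator contracts: determinism, climate coherence, known ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from climniche.climate_space import fit_climate_transform, to_env_space
from climniche.grids import BIOCLIM_VARS, GridSpec
from climniche.synthetic import (
    DEFAULT_ES2_POOL,
    FutureDeltaSpec,
    TrueNiche,
    generate_current_climate,
    generate_future_ensemble,
    generate_service_catalogue,
    generate_virtual_species,
)


def test_same_seed_is_bit_identical_and_seed_change_matters():
    spec = GridSpec(12, 15, nodata_fraction=0.1)
    a = generate_current_climate(spec, seed=5)
    b = generate_current_climate(spec, seed=5)
    c = generate_current_climate(spec, seed=6)
    np.testing.assert_array_equal(a.data, b.data)
    np.testing.assert_array_equal(a.mask, b.mask)
    assert not np.array_equal(
        a.data[:, a.mask & c.mask], c.data[:, a.mask & c.mask]
    )


def test_flat_gradients_and_zero_noise_give_constant_layers():
    stack = generate_current_climate(
        GridSpec(8, 8), seed=0, relief=0.0, moisture_range=0.0, noise_sd=0.0
    )
    for i in range(stack.n_layers):
        vals = stack.data[i][stack.mask]
        assert np.ptp(vals) == 0.0, stack.names[i]


def test_temperature_follows_configured_lapse_exactly():
    # with an explicit elevation field and zero noise the lapse is exact,
    # so higher cells are strictly colder
    spec = GridSpec(6, 6)
    elev = np.linspace(0.0, 3.0, 36).reshape(6, 6)
    stack = generate_current_climate(
        spec, seed=1, noise_sd=0.0, elevation=elev, base_temp=24.0, lapse_rate=6.0
    )
    np.testing.assert_allclose(stack.layer("BIO1"), 24.0 - 6.0 * elev)
    flat = stack.layer("BIO1").ravel()
    assert np.all(np.diff(flat) < 0)


@pytest.mark.parametrize("seed", [3, 4])
def test_bioclim_coherence_current_and_future(seed):
    spec = GridSpec(15, 15, nodata_fraction=0.2)
    current = generate_current_climate(spec, seed=seed)
    deltas = FutureDeltaSpec(n_gcms=2)
    futures = generate_future_ensemble(current, deltas, seed=seed)
    for stack in [current, *futures.values()]:
        m = stack.mask
        assert tuple(stack.names) == BIOCLIM_VARS
        np.testing.assert_array_equal(stack.mask, current.mask)
        assert np.all(stack.layer("BIO5")[m] >= stack.layer("BIO1")[m])
        assert np.all(stack.layer("BIO1")[m] >= stack.layer("BIO6")[m])
        for name in ("BIO12", "BIO13", "BIO14", "BIO15"):
            assert np.all(stack.layer(name)[m] >= 0)


def test_refuses_nodata_fraction_leaving_under_two_cells():
    with pytest.raises(ValueError, match="fewer than 2 valid cells"):
        generate_current_climate(GridSpec(1, 2, nodata_fraction=0.5), seed=0)


def test_identity_deltas_reproduce_current_exactly():
    current = generate_current_climate(GridSpec(10, 10), seed=2)
    deltas = FutureDeltaSpec(
        periods=(2050,),
        rcps=(8.5,),
        mean_offset={(2050, 8.5): 0.0},
        seasonality_inflation={(2050, 8.5): 1.0},
        n_gcms=1,
        gcm_noise_sd=0.0,
    )
    futures = generate_future_ensemble(current, deltas, seed=9)
    (stack,) = futures.values()
    np.testing.assert_array_equal(stack.data, current.data)


def test_future_ensemble_counts_scenarios_times_gcms():
    current = generate_current_climate(GridSpec(5, 5), seed=2)
    futures = generate_future_ensemble(
        current, FutureDeltaSpec(n_gcms=10), seed=1
    )
    assert len(futures) == 2 * 4 * 10
    assert {p for p, _, _ in futures} == {2050, 2070}
    assert {r for _, r, _ in futures} == {2.6, 4.5, 6.0, 8.5}


def test_mean_warming_matches_configured_offset():
    current = generate_current_climate(GridSpec(20, 20), seed=7)
    offset, sd, n_gcms = 2.5, 0.3, 8
    deltas = FutureDeltaSpec(
        periods=(2070,),
        rcps=(8.5,),
        mean_offset={(2070, 8.5): offset},
        seasonality_inflation={(2070, 8.5): 1.0},
        n_gcms=n_gcms,
        gcm_noise_sd=sd,
    )
    futures = generate_future_ensemble(current, deltas, seed=21)
    diffs = [
        np.mean(f.layer("BIO1")[f.mask] - current.layer("BIO1")[current.mask])
        for f in futures.values()
    ]
    # each GCM's anomaly field is zero-mean over the grid up to its spatial
    # structure; the ensemble mean must recover the offset within 3 SE
    se = sd / np.sqrt(n_gcms)
    assert abs(np.mean(diffs) - offset) < 3 * se


class TestVirtualSpecies:
    def test_unsupported_niche_is_refused(self, env):
        far = TrueNiche(
            species_id="ghost",
            mu_true=(1e4, 1e4, 1e4),
            sigma_true=tuple(map(tuple, np.eye(3) * 1e-6)),
            n_occurrences=5,
        )
        with pytest.raises(ValueError, match="all cell weights are zero"):
            generate_virtual_species(env, [far], seed=0)

    def test_exhaustive_sampling_hits_every_valid_cell_once(self, env):
        scores = env.scores()
        broad = TrueNiche(
            species_id="everywhere",
            mu_true=tuple(scores.mean(axis=0)),
            sigma_true=tuple(map(tuple, np.cov(scores, rowvar=False) * 25.0)),
            n_occurrences=scores.shape[0],
        )
        occ = generate_virtual_species(env, [broad], seed=3)
        assert len(occ) == scores.shape[0]
        rows, cols, inside = env.grid.locate(
            occ["decimalLongitude"].to_numpy(), occ["decimalLatitude"].to_numpy()
        )
        assert inside.all()
        cells = set(zip(rows, cols))
        assert len(cells) == scores.shape[0]
        assert all(env.mask[r, c] for r, c in cells)

    def test_occurrence_mean_matches_enumerated_weighted_distribution(
        self, make_pc_stack
    ):
        # dense symmetric score grid centered on the niche: the exact
        # weighted sampling distribution has mean mu_true by symmetry, and
        # its per-axis sd comes from enumeration over cells
        n_side, k = 70, 2
        axis = np.linspace(-4, 4, n_side)
        xx, yy = np.meshgrid(axis, axis)
        scores = np.column_stack([xx.ravel(), yy.ravel()])
        stack = make_pc_stack(scores, n_side, n_side)
        mu = np.array([0.0, 0.0])
        sigma = np.array([[1.0, 0.3], [0.3, 0.8]])
        n_occ = 400
        niche = TrueNiche(
            "virt", tuple(mu), tuple(map(tuple, sigma)), n_occurrences=n_occ
        )
        occ = generate_virtual_species(stack, [niche], seed=12)
        rows, cols, _ = stack.grid.locate(
            occ["decimalLongitude"].to_numpy(), occ["decimalLatitude"].to_numpy()
        )
        pts = np.column_stack(
            [stack.data[0, rows, cols], stack.data[1, rows, cols]]
        )
        diff = scores - mu
        d2 = np.einsum("ij,ji->i", diff, np.linalg.solve(sigma, diff.T))
        w = stats.chi2.sf(d2, df=k)
        w = w / w.sum()
        exact_mean = w @ scores
        exact_var = w @ (scores - exact_mean) ** 2
        np.testing.assert_allclose(exact_mean, mu, atol=1e-12)
        se = np.sqrt(exact_var / n_occ)
        assert np.all(np.abs(pts.mean(axis=0) - mu) < 3 * se)

    def test_replicate_frequencies_match_selection_weights(self, make_pc_stack):
        # single-occurrence replicates make without-replacement sampling
        # identical to the exact weight distribution: chi-square GOF holds
        scores = np.column_stack(
            [np.repeat(np.linspace(-1, 1, 3), 3), np.tile(np.linspace(-1, 1, 3), 3)]
        )
        stack = make_pc_stack(scores, 3, 3)
        niche = TrueNiche("r", (0.0, 0.0), ((1.0, 0.0), (0.0, 1.0)), 1)
        counts = np.zeros(9)
        n_rep = 400
        for rep in range(n_rep):
            occ = generate_virtual_species(stack, [niche], seed=1000 + rep)
            r, c, _ = stack.grid.locate(
                occ["decimalLongitude"].to_numpy()[0],
                occ["decimalLatitude"].to_numpy()[0],
            )
            counts[int(r) * 3 + int(c)] += 1
        diff = scores
        d2 = np.einsum("ij,ij->i", diff, diff)
        w = stats.chi2.sf(d2, df=2)
        expected = n_rep * w / w.sum()
        _, p = stats.chisquare(counts, expected)
        assert p > 0.01


class TestServiceCatalogue:
    def test_single_service_per_species_counts(self):
        cat = generate_service_catalogue(
            ["a", "b", "c"], services_per_species=(1, 1), seed=4
        )
        assert len(cat) == 3
        assert cat["species"].value_counts().max() == 1

    def test_same_seed_identical(self):
        ids = [f"s{i}" for i in range(10)]
        a = generate_service_catalogue(ids, seed=8)
        b = generate_service_catalogue(ids, seed=8)
        pd.testing.assert_frame_equal(a, b)

    def test_default_pool_and_median_two_services(self):
        # the default pool spans 19 level-2 services in 4 categories and the
        # default per-species range gives a median of two services
        assert len(DEFAULT_ES2_POOL) == 19
        assert len({es1 for es1, _ in DEFAULT_ES2_POOL}) == 4
        ids = [f"sp{i}" for i in range(300)]
        cat = generate_service_catalogue(ids, seed=5)
        per_species = cat.groupby("species")["es_level2"].nunique()
        assert per_species.median() == 2

    def test_pool_overflow_refused(self):
        with pytest.raises(ValueError, match="exceeds pool size"):
            generate_service_catalogue(
                ["a"], es2_pool=DEFAULT_ES2_POOL[:3], services_per_species=(1, 5)
            )
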