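import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from habsuit.envelope import (
    EnvelopeSpec,
    build_envelope,
    buffer_populations,
    envelope_area_km2,
    envelope_mask,
    group_populations,
    landscape_inhabitation,
    landscape_preference,
    preferred_range,
)
from habsuit.grid import (
    CategoricalGridLayer,
    GridError,
    LayerStack,
    OccurrenceSet,
    extract_values,
    haversine_km,
)
from habsuit.synth import SyntheticConfig, TruthSpec, generate_environment, generate_occurrences, truth_mask

from .conftest import make_layer


def _occ_at(coords):
    lons, lats = zip(*coords)
    return OccurrenceSet(list(lons), list(lats), [f"o{i}" for i in range(len(coords))])


def _brute_force_groups(occ, linkage_km):
    """All-pairs union-find oracle for single-linkage components."""
    n = len(occ)
    labels = list(range(n))
    changed = True
    while changed:
        changed = False
        for i in range(n):
            for j in range(n):
                if labels[i] != labels[j] and haversine_km(
                    occ.lons[i], occ.lats[i], occ.lons[j], occ.lats[j]
                ) <= linkage_km:
                    lo = min(labels[i], labels[j])
                    hi = max(labels[i], labels[j])
                    labels = [lo if l == hi else l for l in labels]
                    changed = True
    groups = {}
    for i, l in enumerate(labels):
        groups.setdefault(l, set()).add(i)
    return {frozenset(g) for g in groups.values()}


class TestGrouping:
    def test_two_points_5km_one_population(self):
        occ = _occ_at([(0.0, 55.0), (0.0, 55.0 + 5.0 / 111.1949)])
        assert len(group_populations(occ, 10.0)) == 1

    def test_two_points_15km_two_populations(self):
        occ = _occ_at([(0.0, 55.0), (0.0, 55.0 + 15.0 / 111.1949)])
        assert len(group_populations(occ, 10.0)) == 2

    def test_chain_links_transitively(self):
        step = 8.0 / 111.1949
        occ = _occ_at([(0.0, 55.0), (0.0, 55.0 + step), (0.0, 55.0 + 2 * step)])
        d02 = haversine_km(0.0, 55.0, 0.0, 55.0 + 2 * step)
        assert d02 > 10.0  # endpoints not directly linked
        assert len(group_populations(occ, 10.0)) == 1

    def test_population_ids_ordered_south_to_north(self):
        occ = _occ_at([(0.0, 58.0), (0.0, 50.0), (1.0, 54.0)])
        pops = group_populations(occ, 10.0)
        south_lats = [min(occ.lats[i] for i in p.member_idx) for p in pops.populations]
        assert south_lats == sorted(south_lats)
        assert [p.pid for p in pops.populations] == ["P1", "P2", "P3"]

    def test_every_occurrence_in_exactly_one_population(self, small_occ):
        pops = group_populations(small_occ, 10.0)
        seen = [i for p in pops.populations for i in p.member_idx]
        assert sorted(seen) == list(range(len(small_occ)))

    def test_empty_errors(self):
        with pytest.raises(GridError):
            group_populations(OccurrenceSet([], [], []), 10.0)

    @given(st.integers(0, 10_000), st.integers(2, 50))
    @settings(max_examples=40, deadline=None)
    def test_matches_brute_force_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        occ = OccurrenceSet(
            rng.uniform(-1.0, 1.0, n),
            rng.uniform(54.0, 56.0, n),
            [f"p{i}" for i in range(n)],
        )
        pops = group_populations(occ, 10.0)
        got = {frozenset(int(i) for i in p.member_idx) for p in pops.populations}
        assert got == _brute_force_groups(occ, 10.0)

    def test_land_barrier_splits(self):
        # two close points with a land wall between them
        vals = np.zeros((10, 10))
        land = np.zeros((10, 10), bool)
        land[:, 5] = True
        layer = make_layer(vals, origin_lon=0.0, origin_lat=55.0, cell_size=0.01, name="v")
        stack = LayerStack({"v": layer}, land)
        occ = _occ_at([(0.02, 54.95), (0.08, 54.95)])
        assert len(group_populations(occ, 10.0)) == 1
        assert len(group_populations(occ, 10.0, land_barrier_stack=stack)) == 2


class TestBuffer:
    def _sea_stack(self, shape=(60, 60), cell=0.01, origin=(0.0, 55.3)):
        layer = make_layer(np.zeros(shape), origin_lon=origin[0], origin_lat=origin[1], cell_size=cell, name="v")
        return LayerStack({"v": layer})

    def test_single_point_disk_area(self):
        stack = self._sea_stack()
        occ = _occ_at([(0.3, 55.0)])
        pops = buffer_populations(group_populations(occ, 10.0), stack, radius_km=1.0)
        assert pops.populations[0].footprint_area_km2 == pytest.approx(math.pi, rel=0.01)

    def test_coincident_points_idempotent(self):
        stack = self._sea_stack()
        occ = OccurrenceSet([0.3, 0.3], [55.0, 55.0], ["a", "b"])
        pops = buffer_populations(group_populations(occ, 10.0), stack, radius_km=1.0)
        assert pops.populations[0].footprint_area_km2 == pytest.approx(math.pi, rel=0.01)

    def test_footprint_on_land_empty_with_warning(self, caplog):
        layer = make_layer(np.zeros((20, 20)), origin_lon=0.0, origin_lat=55.2, cell_size=0.01, name="v")
        stack = LayerStack({"v": layer}, np.ones((20, 20), bool))  # all land
        occ = _occ_at([(0.1, 55.1)])
        with caplog.at_level("WARNING"):
            pops = buffer_populations(group_populations(occ, 10.0), stack, radius_km=1.0)
        assert not pops.populations[0].footprint_cells.any()
        assert any("land" in m for m in caplog.messages)

    def test_footprint_clipped_to_sea(self):
        stack = self._sea_stack()
        occ = _occ_at([(0.3, 55.0)])
        pops = buffer_populations(group_populations(occ, 10.0), stack, radius_km=1.0)
        cells = pops.populations[0].footprint_cells
        assert cells.any()
        assert not (cells & stack.land_mask).any()


class TestPreferredRange:
    def test_five_values_type7(self):
        assert preferred_range([0, 1, 2, 3, 4]) == (1.0, 3.0)

    def test_constant(self):
        assert preferred_range([5, 5, 5]) == (5.0, 5.0)

    def test_eight_values_type7(self):
        assert preferred_range([1, 2, 3, 4, 5, 6, 7, 8]) == (2.75, 6.25)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            preferred_range([])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=100))
    @settings(max_examples=100, deadline=None)
    def test_interval_within_data_range(self, values):
        lo, hi = preferred_range(values)
        assert min(values) <= lo <= hi <= max(values)


class _FakePop:
    def __init__(self, cells):
        self.footprint_cells = cells
        self.pid = "P"


class TestLandscapePreference:
    def _landscape(self, codes):
        codes = np.asarray(codes)
        return CategoricalGridLayer(
            "landscape", codes, np.zeros(codes.shape, bool), 0.0, float(codes.shape[0]), 1.0,
            legend={int(c): str(c) for c in np.unique(codes)},
        )

    def _popset(self, cell_masks):
        from habsuit.envelope import PopulationSet

        occ = OccurrenceSet([0.0], [0.0], ["x"])
        ps = PopulationSet(occ, [_FakePop(np.asarray(m, bool)) for m in cell_masks], 10.0)
        return ps

    def test_all_populations_on_one_code(self):
        landscape = self._landscape([[2, 2], [2, 2]])
        pops = self._popset([[[1, 0], [0, 0]], [[0, 0], [0, 1]]])
        assert landscape_preference(pops, landscape) == frozenset({2})

    def test_median_rule(self):
        # fractions: A=1.0, B=0.5, C=0.25 -> median 0.5 -> preferred {A, B}
        landscape = self._landscape([[0, 1, 2]])
        pops = self._popset(
            [
                [[True, True, True]],
                [[True, True, False]],
                [[True, False, False]],
                [[True, False, False]],
            ]
        )
        fracs, med, mx = landscape_inhabitation(pops, landscape)
        assert fracs == {0: 1.0, 1: 0.5, 2: 0.25}
        assert med == 0.5 and mx == 1.0
        assert landscape_preference(pops, landscape) == frozenset({0, 1})

    def test_single_population_prefers_everything_it_touches(self):
        landscape = self._landscape([[0, 1, 2]])
        pops = self._popset([[[True, True, False]]])
        assert landscape_preference(pops, landscape) == frozenset({0, 1})

    def test_geometry_mismatch_errors(self):
        landscape = self._landscape([[0, 1]])
        pops = self._popset([[[True], [False]]])
        with pytest.raises(GridError, match="match"):
            landscape_preference(pops, landscape)


class TestBuildEnvelope:
    def test_recovery_within_truth(self, small_stack, small_occ, truth):
        env = build_envelope(small_stack, small_occ)
        for var, (lo, hi) in truth.intervals.items():
            elo, ehi = env.continuous_ranges[var]
            assert lo <= elo <= ehi <= hi, var
        assert env.preferred_landscape <= truth.preferred_landscape

    def test_schema_lists_all_variables(self, small_stack, small_occ):
        env = build_envelope(small_stack, small_occ)
        assert set(env.continuous_ranges) == {
            "temperature", "bathymetry", "slope", "salinity", "current_speed",
        }
        assert env.provenance["n_occurrences"] == len(small_occ)

    def test_single_cell_occurrences_zero_width(self, small_stack, small_occ):
        one = small_occ.subset([0])
        df = extract_values(small_stack, one)
        clones = OccurrenceSet(
            np.repeat(one.lons, 5), np.repeat(one.lats, 5), [f"c{i}" for i in range(5)]
        )
        env = build_envelope(small_stack, clones)
        for var, (lo, hi) in env.continuous_ranges.items():
            assert lo == hi == pytest.approx(float(df[var].iloc[0]))

    def test_table_report_shape(self, small_stack, small_occ):
        env = build_envelope(small_stack, small_occ)
        table = env.to_table(small_stack["landscape"].legend)
        assert set(table.columns) == {"layer", "preferred_range"}
        assert (table["layer"] == "landscape").sum() == len(env.preferred_landscape)

    def test_round_trip_dict(self, small_stack, small_occ):
        env = build_envelope(small_stack, small_occ)
        back = EnvelopeSpec.from_dict(env.to_dict())
        assert back.continuous_ranges == env.continuous_ranges
        assert back.preferred_landscape == env.preferred_landscape


class TestEnvelopeMask:
    def test_vacuous_envelope_covers_all_sea(self, small_stack):
        env = EnvelopeSpec(
            continuous_ranges={
                name: (
                    float(np.nanmin(small_stack[name].values)) - 1,
                    float(np.nanmax(small_stack[name].values)) + 1,
                )
                for name in small_stack.continuous_names()
            },
            preferred_landscape=frozenset(range(4)),
        )
        mask = envelope_mask(small_stack, env)
        assert np.array_equal(mask.values > 0, small_stack.valid_mask())

    def test_impossible_interval_empty(self, small_stack, small_occ):
        env = build_envelope(small_stack, small_occ)
        env.continuous_ranges["temperature"] = (1000.0, 1000.1)
        mask = envelope_mask(small_stack, env)
        assert mask.values.sum() == 0
        assert envelope_area_km2(mask) == 0.0

    def test_dropping_landscape_never_shrinks(self, small_stack, small_occ):
        env = build_envelope(small_stack, small_occ)
        with_lc = envelope_mask(small_stack, env)
        no_lc = envelope_mask(
            small_stack,
            EnvelopeSpec(env.continuous_ranges, frozenset(range(4))),
        )
        assert ((with_lc.values > 0) <= (no_lc.values > 0)).all()

    def test_antitone_in_intervals(self, small_stack, small_occ):
        env = build_envelope(small_stack, small_occ)
        base = envelope_mask(small_stack, env).values > 0
        lo, hi = env.continuous_ranges["salinity"]
        mid = (lo + hi) / 2
        tightened = EnvelopeSpec(
            {**env.continuous_ranges, "salinity": (lo, mid)}, env.preferred_landscape
        )
        tight = envelope_mask(small_stack, tightened).values > 0
        assert (tight <= base).all()

    def test_missing_variable_errors(self, small_stack, small_occ):
        env = build_envelope(small_stack, small_occ)
        env.continuous_ranges["oxygen"] = (0.0, 1.0)
        with pytest.raises(GridError, match="oxygen"):
            envelope_mask(small_stack, env)

    def test_mask_subset_of_truth_region(self, small_stack, small_occ, truth):
        # recovery: envelope cells satisfy the generating truth
        env = build_envelope(small_stack, small_occ)
        mask = envelope_mask(small_stack, env).values > 0
        tm = truth_mask(small_stack, truth)
        assert (mask <= tm).all()

    def test_area_non_increasing_under_warming(self, small_stack, small_occ):
        from habsuit.scenarios import apply_scenario

        env = build_envelope(small_stack, small_occ)
        areas = []
        for dt in (0.0, 0.5, 1.0, 2.0, 3.0):
            warmed = apply_scenario(small_stack, dt)
            areas.append(envelope_area_km2(envelope_mask(warmed, env)))
        assert all(a >= b for a, b in zip(areas, areas[1:]))
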