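import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import timbersim as ts
from timbersim import harvest as hv
from timbersim.harvest import HarvestMode
from timbersim.landscape import Zoning
from timbersim.runner import ScenarioConfig

from _oracles import greedy_allocation
from conftest import uniform_grid


class TestMaxRilRemoval:
    def test_regulatory_cap(self):
        assert hv.max_ril_removal(0.86, 30) == pytest.approx(25.8)

    def test_zero_intensity(self):
        assert hv.max_ril_removal(0.0, 30) == 0.0

    def test_identity_scale(self):
        assert hv.max_ril_removal(1.0, 10) == 10.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            hv.max_ril_removal(-0.1, 30)


class TestPartitionFmus:
    def test_exact_block(self):
        # one complete management block: 270 cells -> 30 annual units of 9
        mask = np.zeros((15, 18), dtype=bool)
        mask[:] = True
        part = hv.partition_fmus(mask, 27_000.0, 30, 100.0)
        assert part.fmu_id.max() == 0
        counts = np.bincount(part.apu_index[mask])
        assert counts[0] == 0
        assert (counts[1:31] == 9).all()
        assert len(counts) == 31

    def test_apu_cell_count_default(self):
        # 900 ha at 100 ha/cell = 9 cells per annual unit
        assert 27_000 // 100 // 30 == 9

    def test_apus_are_contiguous_subblocks(self):
        mask = np.ones((15, 18), dtype=bool)
        part = hv.partition_fmus(mask, 27_000.0, 30, 100.0)
        for apu in range(1, 31):
            rows, cols = np.nonzero(part.apu_index == apu)
            assert rows.max() - rows.min() == 2 and cols.max() - cols.min() == 2

    def test_truncated_fmu(self, caplog):
        mask = np.zeros((1, 5), dtype=bool)
        mask[0, :] = True
        with caplog.at_level("WARNING", logger="timbersim.harvest"):
            part = hv.partition_fmus(mask, 27_000.0, 30, 100.0)
        assert "truncated" in caplog.text
        idx = part.apu_index[mask]
        assert (idx >= 1).all() and (np.bincount(idx)[1:] <= 1).all()

    def test_every_ril_cell_assigned(self):
        rng = np.random.default_rng(4)
        mask = rng.random((40, 40)) < 0.6
        part = hv.partition_fmus(mask, 27_000.0, 30, 100.0)
        assert (part.fmu_id[mask] >= 0).all()
        assert (part.apu_index[mask] >= 1).all()
        assert (part.apu_index[~mask] == 0).all()
        assert (part.fmu_id[~mask] == -1).all()

    def test_complete_fmus_have_equal_apus(self):
        mask = np.ones((30, 36), dtype=bool)  # four complete blocks
        part = hv.partition_fmus(mask, 27_000.0, 30, 100.0)
        for fid in np.unique(part.fmu_id[part.fmu_id >= 0]):
            counts = np.bincount(part.apu_index[part.fmu_id == fid], minlength=31)
            assert (counts[1:] == 9).all()

    def test_apu_below_one_cell(self):
        mask = np.ones((10, 10), dtype=bool)
        with pytest.raises(hv.ConfigurationError):
            hv.partition_fmus(mask, 2_000.0, 30, 100.0)

    def test_deterministic(self):
        mask = np.random.default_rng(1).random((25, 25)) < 0.5
        p1 = hv.partition_fmus(mask, 27_000.0, 30, 100.0, seed=5)
        p2 = hv.partition_fmus(mask, 27_000.0, 30, 100.0, seed=5)
        np.testing.assert_array_equal(p1.apu_index, p2.apu_index)
        np.testing.assert_array_equal(p1.fmu_id, p2.fmu_id)


class TestAssignModes:
    def test_scenario_table(self):
        zoning = np.array([[int(z) for z in Zoning]], dtype=np.int16)
        legal = hv.assign_modes(zoning, ScenarioConfig.legal())
        illegal = hv.assign_modes(zoning, ScenarioConfig.illegal())
        by_cat_legal = dict(zip(list(Zoning), legal[0]))
        by_cat_illegal = dict(zip(list(Zoning), illegal[0]))
        assert by_cat_illegal[Zoning.UNDESIGNATED_FEDERAL] == HarvestMode.CL
        assert by_cat_illegal[Zoning.UNDESIGNATED_STATE] == HarvestMode.CL
        assert by_cat_illegal[Zoning.PRIVATE_NONPROTECTED] == HarvestMode.CL
        assert by_cat_illegal[Zoning.NATIONAL_FOREST] == HarvestMode.RIL
        assert by_cat_illegal[Zoning.SUSTAINABLE_USE_OTHER] == HarvestMode.RIL
        assert by_cat_legal[Zoning.UNDESIGNATED_FEDERAL] == HarvestMode.RIL
        assert by_cat_legal[Zoning.PRIVATE_NONPROTECTED] == HarvestMode.RIL
        for z in (Zoning.INDIGENOUS, Zoning.STRICTLY_PROTECTED, Zoning.MILITARY):
            assert by_cat_legal[z] == HarvestMode.NONE
            assert by_cat_illegal[z] == HarvestMode.NONE

    def test_missing_category(self):
        zoning = np.full((2, 2), int(Zoning.NATIONAL_FOREST), dtype=np.int16)
        cfg = ScenarioConfig("partial", {Zoning.PRIVATE_NONPROTECTED: HarvestMode.RIL})
        with pytest.raises(hv.ConfigurationError):
            hv.assign_modes(zoning, cfg)

    def test_barrier_zone_cannot_be_opened(self):
        with pytest.raises(hv.ConfigurationError):
            ScenarioConfig("bad", {Zoning.INDIGENOUS: HarvestMode.CL})


class TestEligibility:
    def _setup(self):
        g = uniform_grid(6, volume=30.0)
        mode = np.full(g.shape, int(HarvestMode.RIL), dtype=np.int16)
        mode[:, 3:] = int(HarvestMode.CL)
        mode[0, 0] = int(HarvestMode.NONE)
        part = hv.partition_fmus(mode == HarvestMode.RIL, 27_000.0, 30, 100.0)
        return g, mode, part

    def test_ril_on_rotation(self):
        g, mode, part = self._setup()
        rows, cols = np.nonzero(part.apu_index == 3)
        elig = hv.eligible_cells(g, part, mode, 3)
        assert elig[rows[0], cols[0]]

    def test_ril_single_entry(self):
        g, mode, part = self._setup()
        rows, cols = np.nonzero(part.apu_index == 3)
        part.harvested_flag[rows[0], cols[0]] = True
        elig = hv.eligible_cells(g, part, mode, 3)
        assert not elig[rows[0], cols[0]]

    def test_ril_off_rotation(self):
        g, mode, part = self._setup()
        rows, cols = np.nonzero(part.apu_index == 3)
        elig = hv.eligible_cells(g, part, mode, 7)
        assert not elig[rows[0], cols[0]]

    def test_cl_reentry_allowed(self):
        g, mode, part = self._setup()
        g.volume[2, 4] = 5.0  # partial prior entry left some volume
        elig = hv.eligible_cells(g, part, mode, 7)
        assert elig[2, 4]
        g.volume[2, 4] = 0.0
        assert not hv.eligible_cells(g, part, mode, 7)[2, 4]

    def test_none_never_eligible(self):
        g, mode, part = self._setup()
        for year in (1, 15, 30):
            assert not hv.eligible_cells(g, part, mode, year)[0, 0]

    def test_year_out_of_range(self):
        g, mode, part = self._setup()
        for year in (0, 31):
            with pytest.raises(ValueError):
                hv.eligible_cells(g, part, mode, year)


class TestAllocateHarvest:
    def _instance(self):
        shape = (2, 3)
        eligible = np.ones(shape, dtype=bool)
        rent = np.array([[500.0, 900.0, 100.0], [700.0, 900.0, -50.0]])
        hv_m3 = np.full(shape, 1000.0)
        mode = np.full(shape, int(HarvestMode.CL), dtype=np.int16)
        return eligible, rent, hv_m3, mode

    def test_matches_greedy_oracle(self):
        eligible, rent, hv_m3, mode = self._instance()
        capacity = 2500.0  # covers 2.5 cells
        events = hv.allocate_harvest(7, eligible, rent, hv_m3, capacity, mode)
        cells = [
            (r, c, rent[r, c], hv_m3[r, c])
            for r in range(2)
            for c in range(3)
            if eligible[r, c]
        ]
        oracle = greedy_allocation(cells, capacity)
        assert [(e.row, e.col, e.volume_m3) for e in events] == oracle

    def test_tie_break_row_col(self):
        eligible, rent, hv_m3, mode = self._instance()
        events = hv.allocate_harvest(0, eligible, rent, hv_m3, 1500.0, mode)
        # two cells tie at rent 900: (0,1) comes before (1,1)
        assert (events[0].row, events[0].col) == (0, 1)
        assert (events[1].row, events[1].col) == (1, 1)

    def test_saturation(self):
        eligible, rent, hv_m3, mode = self._instance()
        events = hv.allocate_harvest(0, eligible, rent, hv_m3, 1e9, mode)
        assert len(events) == 5  # every positive-rent cell, not the -50 one
        assert all(e.volume_m3 == 1000.0 for e in events)

    def test_zero_capacity(self):
        eligible, rent, hv_m3, mode = self._instance()
        assert hv.allocate_harvest(0, eligible, rent, hv_m3, 0.0, mode) == []

    def test_negative_capacity(self):
        eligible, rent, hv_m3, mode = self._instance()
        with pytest.raises(ValueError):
            hv.allocate_harvest(0, eligible, rent, hv_m3, -1.0, mode)

    def test_partial_cell_prorated_rent(self):
        eligible, rent, hv_m3, mode = self._instance()
        events = hv.allocate_harvest(0, eligible, rent, hv_m3, 1500.0, mode)
        assert events[1].volume_m3 == 500.0
        assert events[1].rent_brl == pytest.approx(900.0 * 0.5)

    @given(capacity=st.floats(0, 7000), data=st.data())
    @settings(max_examples=40, deadline=None)
    def test_oracle_property(self, capacity, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 1000)))
        shape = (3, 3)
        rent = rng.uniform(-100, 1000, size=shape)
        hv_m3 = rng.uniform(1, 2000, size=shape)
        eligible = rng.random(shape) < 0.8
        mode = np.full(shape, int(HarvestMode.CL), dtype=np.int16)
        events = hv.allocate_harvest(0, eligible, rent, hv_m3, capacity, mode)
        cells = [(r, c, rent[r, c], hv_m3[r, c]) for r, c in zip(*np.nonzero(eligible))]
        oracle = greedy_allocation(cells, capacity)
        assert [(e.row, e.col, pytest.approx(e.volume_m3)) for e in events] == [
            (r, c, pytest.approx(v)) for r, c, v in oracle
        ]
        assert sum(e.volume_m3 for e in events) <= capacity + 1e-9


class TestApplyHarvest:
    def _grid_part(self, volume=40.0, mode=HarvestMode.RIL):
        g = uniform_grid(4, volume=volume)
        mode_map = np.full(g.shape, int(mode), dtype=np.int16)
        part = hv.partition_fmus(mode_map == HarvestMode.RIL, 27_000.0, 30, 100.0)
        return g, mode_map, part

    def test_ril_cap_leaves_residual(self):
        g, _, part = self._grid_part(40.0, HarvestMode.RIL)
        ev = hv.HarvestEvent(1, 1, 0, HarvestMode.RIL, 2580.0, 1.0)
        hv.apply_harvest(g, [ev], part)
        assert g.volume[1, 1] == pytest.approx(40.0 - 25.8)
        assert g.volume[1, 1] == pytest.approx(14.2)
        assert part.harvested_flag[1, 1]

    def test_cl_full_removal(self):
        g, _, part = self._grid_part(40.0, HarvestMode.CL)
        ev = hv.HarvestEvent(1, 1, 0, HarvestMode.CL, 4000.0, 1.0)
        hv.apply_harvest(g, [ev], part)
        assert g.volume[1, 1] == 0.0
        assert not part.harvested_flag[1, 1]

    def test_none_mode_rejected(self):
        g, _, part = self._grid_part()
        ev = hv.HarvestEvent(1, 1, 0, HarvestMode.NONE, 100.0, 1.0)
        with pytest.raises(hv.ConsistencyError):
            hv.apply_harvest(g, [ev], part)

    def test_over_removal_rejected(self):
        g, _, part = self._grid_part(10.0, HarvestMode.CL)
        ev = hv.HarvestEvent(1, 1, 0, HarvestMode.CL, 2000.0, 1.0)
        with pytest.raises(hv.ConsistencyError):
            hv.apply_harvest(g, [ev], part)

    def test_double_entry_rejected(self):
        g, _, part = self._grid_part(40.0, HarvestMode.RIL)
        ev = hv.HarvestEvent(1, 1, 0, HarvestMode.RIL, 100.0, 1.0)
        hv.apply_harvest(g, [ev], part)
        with pytest.raises(hv.ConsistencyError):
            hv.apply_harvest(g, [ev], part)

    def test_conservation(self):
        g, _, part = self._grid_part(40.0, HarvestMode.CL)
        initial = g.total_stock_m3()
        events = [hv.HarvestEvent(r, c, 0, HarvestMode.CL, 1000.0, 1.0) for r in range(2) for c in range(2)]
        hv.apply_harvest(g, events, part)
        removed = sum(e.volume_m3 for e in events)
        assert g.total_stock_m3() + removed == pytest.approx(initial)
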