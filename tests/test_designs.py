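import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metphase.designs import (
    DesignError,
    EMPTY,
    LAB_COLUMNS_SCHEMA,
    LabDesign,
    STANDARD_COLUMNS,
    check_confounding,
    feasible_dup_range,
    generate_field_design,
    generate_lab_design,
    plate_plot,
    plot_wells,
)


def cultivars(n):
    return [f"C{i:04d}" for i in range(n)]


class TestFieldDesign:
    @pytest.mark.parametrize(
        "n,blocks,rows,width,total",
        [(648, 5, 8, 81, 405), (856, 5, 8, 107, 535), (8, 1, 8, 1, 1)],
    )
    def test_layout_dimensions(self, n, blocks, rows, width, total):
        fd = generate_field_design(cultivars(n), blocks, rows, seed=1)
        assert fd.block_width == width
        assert fd.n_columns == total

    def test_no_empty_when_capacity_matches(self):
        fd = generate_field_design(cultivars(8), 1, 8, seed=1)
        assert (fd.table["cultivar"] != EMPTY).all()

    def test_duplicate_ids_rejected(self):
        with pytest.raises(DesignError, match="C0001"):
            generate_field_design(["C0001", "C0002", "C0001"], 1, 8, seed=0)

    def test_each_cultivar_once_per_block(self):
        fd = generate_field_design(cultivars(30), 3, 8, seed=2)
        for b in range(1, 4):
            assert fd.block_cultivars(b) == cultivars(30)

    def test_empty_count_per_block(self):
        fd = generate_field_design(cultivars(30), 3, 8, seed=2)
        per_block = fd.table[fd.table["cultivar"] == EMPTY].groupby("block").size()
        assert (per_block == 8 * fd.block_width - 30).all()

    def test_blocks_occupy_contiguous_columns(self):
        fd = generate_field_design(cultivars(30), 3, 8, seed=2)
        for b in range(1, 4):
            cols = fd.table.loc[fd.table["block"] == b, "field_column"]
            lo, hi = cols.min(), cols.max()
            assert (lo, hi) == ((b - 1) * fd.block_width + 1, b * fd.block_width)

    def test_reproducible_from_seed(self):
        a = generate_field_design(cultivars(50), 2, 8, seed=7)
        b = generate_field_design(cultivars(50), 2, 8, seed=7)
        pd.testing.assert_frame_equal(a.table, b.table)
        c = generate_field_design(cultivars(50), 2, 8, seed=8)
        assert not a.table.equals(c.table)

    @given(n=st.integers(2, 120), blocks=st.integers(1, 4), seed=st.integers(0, 10))
    @settings(max_examples=20, deadline=None)
    def test_invariants_random_sizes(self, n, blocks, seed):
        fd = generate_field_design(cultivars(n), blocks, 8, seed=seed)
        assigned = fd.table[fd.table["cultivar"] != EMPTY]
        # each cultivar exactly once per block
        counts = assigned.groupby(["block", "cultivar"]).size()
        assert (counts == 1).all()
        assert len(assigned) == n * blocks


class TestPlateGeometry:
    def test_plot_wells_single_column(self):
        for plot in range(1, 25):
            wells = plot_wells(plot)
            assert len(wells) == 4
            assert len({c for _, c in wells}) == 1

    def test_standard_plots_in_standard_columns(self):
        assert {plate_plot(c, h) for c in STANDARD_COLUMNS for h in (0, 1)} == {21, 22, 23, 24}


@pytest.fixture(scope="module")
def lab():
    return generate_lab_design(
        {b: cultivars(100) for b in (1, 2)}, dup_count=4, plates_per_day=4, seed=9
    )


@pytest.fixture(scope="module")
def field():
    return generate_field_design(cultivars(80), 1, 8, seed=1, trial="t1")


class TestLabDesign:
    def test_660_samples_33_plates(self):
        ld = generate_lab_design({1: cultivars(640)}, dup_count=20, seed=3)
        assert ld.n_samples == 660
        assert ld.n_plates == 33

    def test_880_samples_44_plates(self):
        ld = generate_lab_design({1: cultivars(840)}, dup_count=40, seed=3)
        assert ld.n_samples == 880
        assert ld.n_plates == 44

    def test_single_plate_case(self):
        ld = generate_lab_design({1: cultivars(20)}, dup_count=0, seed=3)
        assert ld.n_plates == 1
        assert set(ld.table["day"]) == {1}

    def test_infeasible_dup_count_rejected(self):
        # 640 + 10 dups -> 650 -> 33 plates; 10 < ceil(33/2)
        with pytest.raises(DesignError, match=r"\[17, 33\]"):
            generate_lab_design({1: cultivars(640)}, dup_count=10, seed=0)

    def test_feasible_range(self):
        assert feasible_dup_range(33) == (17, 33)

    def test_twenty_test_samples_per_full_plate(self, lab):
        samples = lab.table[~lab.table["is_standard"]].drop_duplicates(["plate", "plate_plot"])
        per_plate = samples.groupby("plate").size()
        # 104 samples -> 5 full plates + one short (4) per block
        assert sorted(per_plate) == [4, 4] + [20] * 10

    def test_one_or_two_duplicates_per_plate(self, lab):
        for b in (1, 2):
            samples = lab.block_samples(b)
            dups = samples[samples["cultivar"].isin(lab.duplicates[b])]
            per_plate = dups.groupby("plate").size()
            assert per_plate.between(1, 2).all()

    def test_duplicate_copies_on_different_plates(self, lab):
        for b in (1, 2):
            samples = lab.block_samples(b)
            dups = samples[samples["cultivar"].isin(lab.duplicates[b])]
            assert (dups.groupby("cultivar")["plate"].nunique() == 2).all()

    def test_duplicate_sample_count(self, lab):
        for b in (1, 2):
            samples = lab.block_samples(b)
            n_dup_samples = samples["cultivar"].isin(lab.duplicates[b]).sum()
            assert n_dup_samples == 2 * 4

    def test_block_multiset_matches_availability(self, lab):
        for b in (1, 2):
            samples = lab.block_samples(b)
            non_dup = samples[samples["copy"] == 1]
            assert sorted(non_dup["cultivar"]) == cultivars(100)

    def test_four_wells_per_sample_two_per_column(self, lab):
        tests = lab.table[~lab.table["is_standard"]]
        per_plot = tests.groupby(["plate", "plate_plot"]).size()
        assert (per_plot == 4).all()
        assert not tests["plate_column"].isin(STANDARD_COLUMNS).any()

    def test_standards_on_every_plate(self, lab):
        std = lab.table[lab.table["is_standard"]]
        per_plate = std.groupby("plate").size()
        assert (per_plate == 16).all()  # 4 standards x 4 wells
        assert set(std["plate_column"]) == set(STANDARD_COLUMNS)

    def test_days_group_consecutive_plates(self, lab):
        days = lab.table.drop_duplicates("plate").set_index("plate")["day"].sort_index()
        assert (days == (days.index - 1) // 4 + 1).all()

    def test_reproducible_from_seed(self):
        a = generate_lab_design({1: cultivars(40)}, dup_count=2, seed=5)
        b = generate_lab_design({1: cultivars(40)}, dup_count=2, seed=5)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_schema_columns(self, lab):
        assert list(lab.table.columns) == LAB_COLUMNS_SCHEMA


def _manual_lab_design(field_design, order):
    """LabDesign whose plate order follows ``order`` over block-1 cultivars."""
    rows = []
    for i, cv in enumerate(order):
        plate, slot = divmod(i, 20)
        plot = 2 * (slot // 2) + slot % 2 + 1
        for prow, pcol in plot_wells(plot):
            rows.append(("t1", 1, 1 + plate // 4, plate + 1, plot, prow, pcol, cv, 1, False))
    table = pd.DataFrame(rows, columns=LAB_COLUMNS_SCHEMA)
    return LabDesign(trial="t1", plates_per_day=4, duplicates={1: []}, table=table)


class TestConfounding:
    def _field_order(self, field):
        sub = field.table[field.table["cultivar"] != EMPTY]
        return list(sub.sort_values(["field_column", "field_row"])["cultivar"])

    def test_identity_order_flagged(self, field):
        # ties (8 samples per field column, 20 per plate) keep |r| just below 1
        lab = _manual_lab_design(field, self._field_order(field))
        diag = check_confounding(field, lab)
        assert diag.loc[0, "spearman_r"] > 0.9
        assert bool(diag.loc[0, "flagged"])

    def test_reversed_order_flagged(self, field):
        lab = _manual_lab_design(field, self._field_order(field)[::-1])
        diag = check_confounding(field, lab)
        assert diag.loc[0, "spearman_r"] < -0.9
        assert bool(diag.loc[0, "flagged"])

    def test_differing_sample_sets_rejected(self, field):
        order = self._field_order(field)
        order[0] = "INTRUDER"
        lab = _manual_lab_design(field, order)
        with pytest.raises(DesignError, match="INTRUDER"):
            check_confounding(field, lab)

    def test_randomised_designs_uncorrelated(self):
        # |rank correlation| below 0.1 in >= 95% of 100 seeds at 660 samples
        field = generate_field_design(cultivars(640), 1, 8, seed=0, trial="t1")
        ok = 0
        for seed in range(100):
            lab = generate_lab_design(
                {1: cultivars(640)}, dup_count=20, seed=seed, trial="t1"
            )
            diag = check_confounding(field, lab)
            if abs(diag.loc[0, "spearman_r"]) < 0.1:
                ok += 1
        assert ok >= 95
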