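"""Per-ASV absolute abundance, clamped growth and cell-count conversion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phagesip import (
    asv_absolute,
    copies_to_cells,
    detection_limit_cells,
    generation_stats,
    growth_table,
    new_copies,
    total_growth_fold,
)


class TestAsvAbsolute:
    @pytest.mark.parametrize(
        "reads, total, copies, expected",
        [
            (303, 3578, 2.47e8, 2.09e7),  # dominant grower at end point
            (0, 3748, 9.78e7, 0.0),
            (148, 3748, 9.78e7, 3.86e6),
        ],
    )
    def test_read_share_of_census(self, reads, total, copies, expected):
        assert asv_absolute(reads, total, copies) == pytest.approx(expected, rel=0.005)

    def test_zero_total_reads_fails(self):
        with pytest.raises(ValueError):
            asv_absolute(0, 0, 1e8)

    @given(
        counts=st.lists(st.integers(0, 1000), min_size=2, max_size=30),
        copies=st.floats(1e3, 1e9),
    )
    @settings(max_examples=50, deadline=None)
    def test_shares_conserve_total(self, counts, copies):
        total = sum(counts)
        if total == 0:
            return
        parts = [asv_absolute(c, total, copies) for c in counts]
        assert sum(parts) == pytest.approx(copies)


class TestGrowthClamping:
    @pytest.mark.parametrize(
        "initial, final, expected",
        [
            (3.86e6, 2.55e6, 0.0),  # net decliner is neglected
            (3.44e6, 4.28e6, 8.4e5),
            (0.0, 2.09e7, 2.09e7),
        ],
    )
    def test_new_copies(self, initial, final, expected):
        assert new_copies(initial, final) == pytest.approx(expected, rel=0.01)

    @given(i=st.floats(0, 1e9), f=st.floats(0, 1e9))
    @settings(max_examples=100, deadline=None)
    def test_never_negative_and_zero_for_decliners(self, i, f):
        out = new_copies(i, f)
        assert out >= 0
        if f <= i:
            assert out == 0


class TestCellConversion:
    @pytest.mark.parametrize(
        "copies, cpn, expected",
        [(2.09e7, 10, 2.09e6), (3.80e6, 1, 3.80e6), (42.0, 1, 42.0)],
    )
    def test_copies_to_cells(self, copies, cpn, expected):
        assert copies_to_cells(copies, cpn) == pytest.approx(expected)

    @given(cells=st.floats(0, 1e9), cpn=st.floats(1, 15))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, cells, cpn):
        assert copies_to_cells(cells * cpn, cpn) == pytest.approx(cells, abs=1e-6)

    def test_sub_unit_copy_number_rejected(self):
        with pytest.raises(ValueError):
            copies_to_cells(1e6, 0.5)


class TestDetectionLimit:
    @pytest.mark.parametrize(
        "reads, copies, cpn, expected",
        [(3748, 9.78e7, 10, 2600.0), (100, 100, 1, 1.0), (1000, 1e6, 4, 250.0)],
    )
    def test_two_significant_figures(self, reads, copies, cpn, expected):
        assert detection_limit_cells(reads, copies, cpn) == expected


class TestGenerationStats:
    def test_single_founder_cell(self):
        gens, minutes = generation_stats(1, 2.09e6, 1375)
        assert gens == pytest.approx(21.0, abs=0.05)
        assert minutes == pytest.approx(65.5, abs=0.1)

    def test_one_doubling(self):
        assert generation_stats(1, 2, 60) == pytest.approx((1.0, 60.0))

    def test_detection_limit_founders(self):
        gens, minutes = generation_stats(2600, 2.09e6, 1375)
        assert gens == pytest.approx(9.65, abs=0.01)
        assert minutes == pytest.approx(142, abs=1)

    def test_no_growth_is_undefined(self):
        with pytest.raises(ValueError):
            generation_stats(100, 100, 60)


@pytest.mark.parametrize(
    "initial, final, expected",
    [(9.78e7, 2.35e8, 2.40), (5.0, 5.0, 1.0), (9.78e7, 2.47e8, 2.53)],
)
def test_total_growth_fold(initial, final, expected):
    assert total_growth_fold(initial, final) == pytest.approx(expected, abs=0.005)


class TestGrowthTable:
    @pytest.fixture()
    def counts(self):
        return pd.DataFrame(
            [
                {"sample_id": "initial", "asv_id": "a", "reads": 100},
                {"sample_id": "initial", "asv_id": "b", "reads": 900},
                {"sample_id": "final_13c", "asv_id": "a", "reads": 500},
                {"sample_id": "final_13c", "asv_id": "b", "reads": 500},
            ]
        )

    def test_conservation_and_clamping(self, counts):
        table = growth_table(
            counts, "initial", "final_13c", 1e8, 2e8,
            genus_of={"a": "ga", "b": "gb"},
            copy_numbers={"ga": 10.0, "gb": 2.0},
        )
        assert table["initial_copies"].sum() == pytest.approx(1e8)
        assert table["final_copies"].sum() == pytest.approx(2e8)
        assert table.loc["a", "new_copies"] == pytest.approx(9e7)
        assert table.loc["b", "new_copies"] == pytest.approx(1e7)
        assert table.loc["a", "new_cells"] == pytest.approx(9e6)
        assert (table["new_copies"] >= 0).all()

    def test_missing_genus_defaults_to_one_copy(self, counts, caplog):
        with caplog.at_level("WARNING"):
            table = growth_table(
                counts, "initial", "final_13c", 1e8, 2e8,
                genus_of={"a": "ga"}, copy_numbers={"ga": 10.0},
            )
        assert table.loc["b", "copies_per_genome"] == 1.0
        assert any("no 16S copy number" in r.message for r in caplog.records)

    def test_absent_sample_is_an_error(self, counts):
        with pytest.raises(ValueError, match="no count rows"):
            growth_table(counts, "initial", "nonexistent", 1e8, 2e8)
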