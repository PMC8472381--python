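"""Carbon ledger: cells to carbon, yield correction, pool shares."""

import dataclasses

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phagesip import (
    CarbonConstants,
    cells_to_carbon,
    contribution,
    mass_balance_table,
    phage_carbon_pool,
    pure_culture_yield,
    total_mass_balance,
)

DEFAULTS = CarbonConstants()


class TestCellsToCarbon:
    @pytest.mark.parametrize(
        "cells, expected",
        [(2.09e6, 6.27e-8), (0.0, 0.0), (1.07e7, 3.21e-7)],
    )
    def test_thirty_femtograms_per_cell(self, cells, expected):
        assert cells_to_carbon(cells, DEFAULTS) == pytest.approx(expected, rel=0.01)

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            cells_to_carbon(-1.0, DEFAULTS)


class TestContribution:
    def test_dominant_grower_draws_five_percent(self):
        row = contribution(6.28e-8, 0.85, DEFAULTS)
        assert row.carbon_13 == pytest.approx(5.33e-8, rel=0.01)
        assert row.contribution == pytest.approx(0.0505, abs=0.001)
        assert round(100 * row.contribution) == 5

    def test_unlabeled_biomass_draws_nothing(self):
        row = contribution(1e-7, 0.0, DEFAULTS)
        assert row.carbon_13 == 0.0
        assert row.contribution == 0.0

    def test_half_labeled_mid_abundance(self):
        row = contribution(1.14e-7, 0.49, DEFAULTS)
        assert row.carbon_13 == pytest.approx(5.6e-8, rel=0.01)
        assert round(100 * row.contribution) == 5

    @given(
        carbon=st.floats(0, 1e-6),
        labeling=st.floats(0, 1),
        scale=st.floats(0.1, 10),
    )
    @settings(max_examples=100, deadline=None)
    def test_linear_in_carbon_and_labeling(self, carbon, labeling, scale):
        base = contribution(carbon, labeling, DEFAULTS)
        assert base.carbon_13 >= 0 and base.contribution >= 0
        scaled = contribution(scale * carbon, labeling, DEFAULTS)
        assert scaled.contribution == pytest.approx(
            scale * base.contribution, rel=1e-9, abs=1e-12
        )

    @given(carbon=st.floats(1e-12, 1e-6), labeling=st.floats(0.01, 1))
    @settings(max_examples=50, deadline=None)
    def test_doubling_yield_halves_contribution(self, carbon, labeling):
        low = contribution(carbon, labeling, dataclasses.replace(DEFAULTS, yield_=0.25))
        high = contribution(carbon, labeling, dataclasses.replace(DEFAULTS, yield_=0.5))
        assert low.contribution == pytest.approx(2 * high.contribution, rel=1e-9)


class TestTotals:
    def test_published_nine_taxon_budget(self):
        """The nine labeled taxa account for ~41% of the labeled pool."""
        cells = [2.09e6, 1.07e7, 0, 2.09e5, 0, 2.94e5, 3.80e6, 8.15e5, 1.21e6]
        levels = [0.85, 0.95, 0.10, 0.14, 0.71, 0.19, 0.49, 0.16, 0.23]
        rows = [
            contribution(cells_to_carbon(c, DEFAULTS), lab, DEFAULTS)
            for c, lab in zip(cells, levels)
        ]
        total = total_mass_balance(rows)
        assert 0.40 <= total <= 0.41
        assert round(100 * total) == 41

    def test_empty_ledger_is_zero(self):
        assert total_mass_balance([]) == 0.0

    def test_single_row_passthrough(self):
        row = contribution(6.28e-8, 0.85, DEFAULTS)
        assert total_mass_balance([row]) == row.contribution


class TestPhagePool:
    def test_labeled_particle_pool(self):
        assert phage_carbon_pool(2.28e10, DEFAULTS) == pytest.approx(3.40e-6, rel=0.005)

    def test_empty_pool(self):
        assert phage_carbon_pool(0, DEFAULTS) == 0.0

    def test_pure_culture_pool(self):
        assert phage_carbon_pool(1e11, DEFAULTS) == pytest.approx(1.49e-5)

    def test_partial_purity_scales_pool(self):
        half = dataclasses.replace(DEFAULTS, phage_label_purity=0.5)
        assert phage_carbon_pool(1e10, half) == pytest.approx(
            0.5 * phage_carbon_pool(1e10, DEFAULTS)
        )


class TestPureCultureYield:
    def test_published_carbon_use_efficiency(self):
        y = pure_culture_yield(1.63e8, 1e11, DEFAULTS)
        assert y == pytest.approx(0.328, abs=0.001)
        assert round(100 * y) == 33

    def test_no_growth_no_yield(self):
        assert pure_culture_yield(0, 1e11, DEFAULTS) == 0.0

    def test_perfect_efficiency_bound(self):
        cells = DEFAULTS.carbon_per_phage * 1e11 / DEFAULTS.carbon_per_cell
        assert pure_culture_yield(cells, 1e11, DEFAULTS) == pytest.approx(1.0)


class TestMassBalanceTable:
    def test_only_taxa_with_labeling_enter_the_ledger(self):
        cells = pd.Series({"a": 1e6, "b": 2e6, "c": 3e6})
        labeling = pd.Series({"a": 0.5, "b": float("nan"), "d": 0.9})
        table = mass_balance_table(cells, labeling, DEFAULTS)
        assert list(table.index) == ["a"]
        assert table.loc["a", "contribution"] == pytest.approx(
            contribution(cells_to_carbon(1e6, DEFAULTS), 0.5, DEFAULTS).contribution
        )
        assert table.loc["a", "contribution_percent"] == round(
            100 * table.loc["a", "contribution"]
        )

    def test_constants_validation(self):
        with pytest.raises(ValueError):
            CarbonConstants(yield_=0.0)
        with pytest.raises(ValueError):
            CarbonConstants(pool_13c=-1.0)
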