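"""Gaussian density fitting, GC fallback and labeling-level conversion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phagesip import (
    GradientConfig,
    asv_dna_per_fraction,
    fit_density_gaussian,
    labeling_level,
    labeling_table,
    theoretical_density,
)

GRID_STEP = 0.0005


def grid_gaussian_mean(x, y, mu_step=GRID_STEP):
    """Brute-force reference fit: exhaustive (mu, sigma) grid search.

    For each candidate (mu, sigma) the amplitude minimising the squared
    error is solved in closed form; the mu of the lowest-SSE cell is
    returned. Deliberately independent of the least-squares code path.
    """
    mus = np.arange(x.min(), x.max() + mu_step / 2, mu_step)
    sigmas = np.arange(0.002, 0.0205, mu_step)
    shapes = np.exp(
        -((x[None, None, :] - mus[:, None, None]) ** 2)
        / (2.0 * sigmas[None, :, None] ** 2)
    )  # (n_mu, n_sigma, n_points)
    denom = (shapes**2).sum(axis=2)
    amp = (shapes * y[None, None, :]).sum(axis=2) / denom
    sse = ((y[None, None, :] - amp[:, :, None] * shapes) ** 2).sum(axis=2)
    i, _ = np.unravel_index(np.argmin(sse), sse.shape)
    return float(mus[i])


def gaussian_points(mu, sigma=0.006, amplitude=5.0, n=12, lo=1.65, hi=1.78):
    x = np.linspace(lo, hi, n)
    return x, amplitude * np.exp(-((x - mu) ** 2) / (2 * sigma**2))


class TestAsvDnaPerFraction:
    @pytest.mark.parametrize(
        "dna, reads, total, expected",
        [(10.0, 50, 500, 1.0), (0.0, 7, 400, 0.0), (8.0, 0, 400, 0.0)],
    )
    def test_proportional_allocation(self, dna, reads, total, expected):
        assert asv_dna_per_fraction(dna, reads, total) == pytest.approx(expected)

    def test_empty_fraction_contributes_no_point(self):
        with pytest.raises(ValueError):
            asv_dna_per_fraction(10.0, 0, 0)


class TestGaussianFit:
    def test_noiseless_recovery_is_exact(self):
        x, y = gaussian_points(mu=1.72)
        fit = fit_density_gaussian(x, y)
        assert fit is not None
        assert fit.mean_density == pytest.approx(1.72, abs=1e-6)
        assert fit.spread == pytest.approx(0.006, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert fit.source == "fitted"

    def test_constant_profile_is_not_a_peak(self):
        """Flat DNA across fractions must not yield a confident fit."""
        x = np.linspace(1.65, 1.78, 12)
        y = np.full_like(x, 3.0)
        fit = fit_density_gaussian(x, y)
        assert fit is None or fit.r_squared < 0.5

    def test_too_few_positive_points(self):
        x = np.linspace(1.65, 1.78, 12)
        y = np.zeros_like(x)
        y[5:8] = [1.0, 4.0, 1.0]
        assert fit_density_gaussian(x, y, min_fit_points=4) is None

    def test_mean_of_noisy_replicates_is_unbiased(self):
        """200 log-normal-noise replicates: mean fitted peak within 0.001."""
        rng = np.random.default_rng(42)
        x, clean = gaussian_points(mu=1.75)
        sigma = np.sqrt(np.log1p(0.10**2))
        mus = []
        for _ in range(200):
            noisy = clean * rng.lognormal(-sigma**2 / 2, sigma, size=clean.shape)
            fit = fit_density_gaussian(x, noisy)
            assert fit is not None
            mus.append(fit.mean_density)
        assert np.mean(mus) == pytest.approx(1.75, abs=0.001)

    def test_matches_grid_search_oracle(self):
        """Least squares agrees with exhaustive grid search within one step."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            mu = rng.uniform(1.68, 1.75)
            x, clean = gaussian_points(mu=mu)
            noisy = clean * rng.lognormal(0.0, 0.1, size=clean.shape)
            fit = fit_density_gaussian(x, noisy)
            assert fit is not None
            assert abs(fit.mean_density - grid_gaussian_mean(x, noisy)) <= GRID_STEP


class TestTheoreticalDensity:
    @pytest.mark.parametrize("gc, rho", [(0.0, 1.660), (0.5, 1.709), (1.0, 1.758)])
    def test_schildkraut_relation(self, gc, rho):
        assert theoretical_density(gc) == pytest.approx(rho)

    def test_gc_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            theoretical_density(1.2)


class TestLabelingLevel:
    def test_published_shift(self):
        res = labeling_level(1.72, 1.75)
        assert res.labeling == pytest.approx(0.833, abs=0.001)
        assert res.flag == "none"

    def test_no_shift_flags_possible_indirect_labeling(self):
        res = labeling_level(1.71, 1.71)
        assert res.labeling == 0.0
        assert res.flag == "possibly_indirect"

    def test_negative_shift_clamps_to_zero(self):
        assert labeling_level(1.72, 1.70).labeling == 0.0

    @given(
        rho=st.floats(1.60, 1.80),
        shift=st.floats(-0.01, 0.05),
        offset=st.floats(-0.02, 0.02),
    )
    @settings(max_examples=100, deadline=None)
    def test_translation_invariance(self, rho, shift, offset):
        a = labeling_level(rho, rho + shift).labeling
        b = labeling_level(rho + offset, rho + shift + offset).labeling
        assert a == pytest.approx(b, abs=1e-9)

    def test_nonfinite_density_rejected(self):
        with pytest.raises(ValueError):
            labeling_level(float("nan"), 1.72)


class TestLabelingTable:
    def _tables(self, mu12, mu13, n=12):
        """Two-bottle fraction data for one ASV plus a broad background."""
        x = np.linspace(1.65, 1.78, n)
        rows_f, rows_c = [], []
        for bottle, mu in (("c12", mu12), ("c13", mu13)):
            asv = 100 * np.exp(-((x - mu) ** 2) / (2 * 0.006**2))
            bg = np.full_like(x, 50.0)
            for j, d in enumerate(x):
                fid = f"F{j:02d}"
                rows_f.append({
                    "bottle": bottle, "fraction_id": fid,
                    "density_g_per_ml": d, "dna_ng": asv[j] + bg[j],
                })
                rows_c.append({"bottle": bottle, "fraction_id": fid,
                               "asv_id": "asvA", "reads": int(round(10 * asv[j]))})
                rows_c.append({"bottle": bottle, "fraction_id": fid,
                               "asv_id": "background", "reads": int(round(10 * bg[j]))})
        return pd.DataFrame(rows_f), pd.DataFrame(rows_c)

    def test_two_bottle_shift_recovered(self):
        fractions, counts = self._tables(mu12=1.70, mu13=1.727)
        table = labeling_table(fractions, counts)
        assert table.loc["asvA", "labeling"] == pytest.approx(0.75, abs=0.02)
        assert bool(table.loc["asvA", "significant"])

    def test_sparse_control_falls_back_to_gc_density(self):
        fractions, counts = self._tables(mu12=1.709, mu13=1.745)
        # starve the control bottle of this ASV's reads: no 12C fit possible
        counts.loc[
            (counts["bottle"] == "c12") & (counts["asv_id"] == "asvA"), "reads"
        ] = 0
        table = labeling_table(fractions, counts, gc_of={"asvA": 0.5})
        assert table.loc["asvA", "density_source_12c"] == "theoretical"
        assert table.loc["asvA", "density_12c"] == pytest.approx(1.709)
        assert table.loc["asvA", "labeling"] == pytest.approx(1.0, abs=0.02)

    def test_no_fallback_without_gc(self):
        fractions, counts = self._tables(mu12=1.70, mu13=1.73)
        counts.loc[
            (counts["bottle"] == "c12") & (counts["asv_id"] == "asvA"), "reads"
        ] = 0
        table = labeling_table(fractions, counts)
        assert table.loc["asvA", "flag"] == "insufficient_data"
        assert not bool(table.loc["asvA", "significant"])

    def test_significance_requires_labeling_and_fit_quality(self):
        fractions, counts = self._tables(mu12=1.70, mu13=1.702)
        table = labeling_table(
            fractions, counts, config=GradientConfig(min_labeling=0.10)
        )
        assert table.loc["asvA", "labeling"] < 0.10
        assert not bool(table.loc["asvA", "significant"])
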