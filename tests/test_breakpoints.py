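import numpy as np
import pandas as pd
import pytest

from elevbreak import (SimulationParams, simulate_mountain, simulate_two_mountains,
                       piecewise_fit, breakpoint_bootstrap, adjacent_turnover,
                       split_density, cross_mountain, consensus_breakpoints)
from elevbreak.breakpoints import BreakpointFit


def _two_segment(n=120, psi=2400.0, b0=1.0, b1=0.002, b2=-0.004, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    x = np.repeat(np.linspace(700, 3760, 18), n // 18 + 1)[:n]
    y = b0 + b1 * x + b2 * np.clip(x - psi, 0, None) + rng.normal(0, noise, n)
    return x, y


class TestPiecewiseFit:
    def test_noiseless_break_recovered_exactly(self):
        x, y = _two_segment()
        fit = piecewise_fit(x, y)
        assert fit.psi == pytest.approx(2400.0, abs=1.0)
        assert fit.sse == pytest.approx(0.0, abs=1e-12)
        assert fit.beta1 == pytest.approx(0.002, abs=1e-9)
        assert fit.beta2 == pytest.approx(-0.004, abs=1e-9)

    def test_grid_search_matches_bruteforce(self):
        """Grid search equals an independently coded per-candidate SSE loop."""
        for seed in range(5):
            x, y = _two_segment(noise=0.4, seed=seed)
            fit = piecewise_fit(x, y, step=10.0)
            best = None
            for cand in np.arange(1800.0, 3000.0 + 5.0, 10.0):
                design = np.column_stack([np.ones_like(x), x,
                                          np.clip(x - cand, 0, None)])
                beta, *_ = np.linalg.lstsq(design, y, rcond=None)
                sse = float(np.sum((y - design @ beta) ** 2))
                if best is None or sse < best[1]:
                    best = (cand, sse)
            assert fit.psi == pytest.approx(best[0])
            assert fit.sse == pytest.approx(best[1], abs=1e-9)

    def test_piecewise_never_worse_than_line(self, rng):
        for _ in range(10):
            x = np.repeat(np.linspace(700, 3760, 18), 4)
            y = rng.normal(size=len(x))
            fit = piecewise_fit(x, y)
            lin = np.polyfit(x, y, 1)
            sse_line = float(np.sum((y - np.polyval(lin, x)) ** 2))
            assert fit.sse <= sse_line + 1e-9

    def test_linear_data_gives_small_slope_change(self):
        rng = np.random.default_rng(7)
        x = np.repeat(np.linspace(700, 3760, 18), 10)
        y = 2.0 + 0.001 * x + rng.normal(0, 0.3, len(x))
        fit = piecewise_fit(x, y)
        assert abs(fit.beta2) < 5e-4
        assert fit.p_improvement > 0.05

    def test_band_outside_data_rejected(self):
        x, y = _two_segment()
        with pytest.raises(ValueError):
            piecewise_fit(x, y, band=(5000.0, 6000.0))


class TestBootstrap:
    def test_noiseless_ci_collapses(self):
        x, y = _two_segment()
        lo, hi, edge = breakpoint_bootstrap(x, y, n_boot=99, seed=0)
        assert lo == pytest.approx(2400.0, abs=1.0)
        assert hi == pytest.approx(2400.0, abs=1.0)
        assert not edge

    def test_same_seed_same_interval(self):
        x, y = _two_segment(noise=0.5, seed=2)
        a = breakpoint_bootstrap(x, y, n_boot=99, seed=11)
        b = breakpoint_bootstrap(x, y, n_boot=99, seed=11)
        assert a == b

    def test_interval_narrows_with_less_noise(self):
        """Bootstrap CI width shrinks (stochastically) as residual noise drops:
        compared over matched seeds at two noise levels."""
        widths = {0.1: [], 1.0: []}
        for seed in range(12):
            for noise in widths:
                x, y = _two_segment(noise=noise, seed=seed)
                lo, hi, _ = breakpoint_bootstrap(x, y, n_boot=99, seed=seed)
                widths[noise].append(hi - lo)
        assert np.mean(widths[0.1]) < np.mean(widths[1.0])

    def test_ci_brackets_estimate_on_default_bundle(self, default_bundle):
        sf = default_bundle.sample_frame
        c2 = np.array(default_bundle.truth["function_coefficients"]["c2"])
        name = default_bundle.truth["function_names"][int(np.argmax(np.abs(c2)))]
        fit = piecewise_fit(sf["elevation"].to_numpy(), sf[name].to_numpy(),
                            n_boot=99, seed=0)
        assert fit.ci_low <= fit.psi <= fit.ci_high


class TestAdjacentTurnover:
    def test_planted_fault_selected(self):
        params = SimulationParams(seed=11, pool_mixing=1.0)
        b = simulate_mountain(params)
        site_elev = b.sample_frame.groupby("site_id")["elevation"].mean()
        prof = adjacent_turnover(b.otu_matrix, b.sample_frame["site_id"], site_elev,
                                 n_perm=99, seed=0)
        assert prof.selected["elev_low"] < params.fault_elev < prof.selected["elev_high"]
        assert (prof.table["pseudo_f"] >= 0).all()

    def test_ranksum_reduces_to_argmax_when_unanimous(self, default_bundle):
        b = default_bundle
        site_elev = b.sample_frame.groupby("site_id")["elevation"].mean()
        prof = adjacent_turnover(b.otu_matrix, b.sample_frame["site_id"], site_elev,
                                 n_perm=99, seed=0)
        in_band = prof.table[(prof.table["boundary_elev"] >= 1800)
                             & (prof.table["boundary_elev"] <= 3000)]
        if (in_band["pseudo_f"].idxmax() == in_band["dissimilarity"].idxmax()):
            top = in_band.loc[in_band["pseudo_f"].idxmax()]
            assert prof.selected["boundary_elev"] == top["boundary_elev"]

    def test_band_without_pairs_rejected(self, default_bundle):
        b = default_bundle
        site_elev = b.sample_frame.groupby("site_id")["elevation"].mean()
        with pytest.raises(ValueError):
            adjacent_turnover(b.otu_matrix, b.sample_frame["site_id"], site_elev,
                              band=(1900.0, 1950.0), n_perm=99, seed=0)


class TestSplitDensity:
    def test_perfect_step_dominates(self):
        rng = np.random.default_rng(0)
        elev = np.repeat(np.linspace(700, 3760, 18), 10)
        step = (elev > 2400).astype(float) * 50
        noise_taxa = rng.random((len(elev), 5))
        m = pd.DataFrame(np.column_stack([step, noise_taxa]))
        res = split_density(m, elev)
        spacing = 180.0
        first = res.splits[res.splits["taxon"] == 0].sort_values("weight").iloc[-1]
        assert abs(first["threshold"] - 2400) <= spacing
        assert abs(res.peak_elev - 2400) <= spacing

    def test_constant_matrix_gives_flat_zero_density(self):
        elev = np.repeat(np.linspace(700, 3760, 18), 10)
        m = pd.DataFrame(np.ones((len(elev), 4)))
        res = split_density(m, elev)
        assert res.splits.empty
        assert np.allclose(res.standardized, 0.0)
        assert res.peak_elev is None

    def test_scale_equivariance_of_thresholds(self, rng):
        elev = np.repeat(np.linspace(700, 3760, 18), 10)
        m = pd.DataFrame(rng.random((len(elev), 6)))
        a = split_density(m, elev).splits
        b = split_density(2.0 * m, elev).splits
        pd.testing.assert_series_equal(a["threshold"], b["threshold"])


class TestCrossMountain:
    @staticmethod
    def _site_level(bundle):
        site = bundle.sample_frame["site_id"]
        m = bundle.otu_matrix.groupby(site).mean()
        elev = bundle.sample_frame.groupby("site_id")["elevation"].mean().loc[m.index]
        return m, elev.to_numpy()

    def test_identical_mountains_flat_profile(self, default_bundle):
        m, elev = self._site_level(default_bundle)
        res = cross_mountain(m, m, elev, elev, n_perm=99, seed=0)
        assert res.flat
        assert np.allclose(res.matched["similarity"], 1.0)
        assert res.min_similarity_elev is None

    def test_minimum_similarity_near_planted_fault(self, site_spacing):
        """Half-spacing offset makes one matched pair straddle the fault; that
        pair has the lowest cross-mountain similarity."""
        a, b = simulate_two_mountains(SimulationParams(seed=4, pool_mixing=1.0),
                                      {"elev_offset": 90.0})
        ma, ea = self._site_level(a)
        mb, eb = self._site_level(b)
        res = cross_mountain(ma, mb, ea, eb, pairing_tol=100.0, n_perm=99, seed=0)
        assert abs(res.min_similarity_elev - 2400.0) <= site_spacing

    def test_slope_table_produced_per_side(self, default_bundle):
        m, elev = self._site_level(default_bundle)
        res = cross_mountain(m, m, elev, elev, breakpoint=2400.0, n_perm=99, seed=0)
        assert set(res.slopes["side"]) == {"below", "above"}
        assert ((res.slopes["p_value"] > 0) & (res.slopes["p_value"] <= 1)).all()


class TestConsensus:
    @staticmethod
    def _fit(psi, p=0.01):
        return BreakpointFit(psi=psi, beta0=0, beta1=0, beta2=0, sse=0, r2=1,
                             p_improvement=p, band=(1800, 3000), n=10)

    def test_single_fit_summary(self):
        out = consensus_breakpoints({"emf": [self._fit(2300.0)]})
        assert out.loc["emf", "mean"] == 2300.0
        assert out.loc["emf", "n_significant"] == 1

    def test_identical_fits_zero_iqr(self):
        out = consensus_breakpoints({"f": [self._fit(2400.0)] * 5})
        assert out.loc["f", "q3"] - out.loc["f", "q1"] == 0.0

    def test_global_mean_is_weighted_facet_mean(self):
        fits = {"a": [self._fit(2000.0), self._fit(2200.0)],
                "b": [self._fit(2600.0)]}
        out = consensus_breakpoints(fits)
        pooled = np.mean([2000.0, 2200.0, 2600.0])
        weighted = (out["mean"] * out["n"]).sum() / out["n"].sum()
        assert weighted == pytest.approx(pooled)
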