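import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from elevbreak import (rarefy, richness, chao1, aggregate_taxa, prevalence_filter,
                       multidiversity, importance_value, plant_biomass)


def _mat(rows, index=None, columns=None):
    rows = np.atleast_2d(rows)
    return pd.DataFrame(rows,
                        index=index or [f"s{i}" for i in range(rows.shape[0])],
                        columns=columns or [f"t{j}" for j in range(rows.shape[1])])


class TestRarefy:
    def test_rows_sum_to_depth_and_subset_of_counts(self, rng):
        counts = _mat(rng.integers(0, 60, size=(6, 30)) + 1)
        out = rarefy(counts, depth=200, seed=0)
        assert (out.sum(axis=1) == 200).all()
        assert (out.to_numpy() <= counts.loc[out.index].to_numpy()).all()

    def test_row_at_depth_unchanged(self):
        row = _mat([[7, 3, 90]])
        out = rarefy(row, depth=100, seed=0)
        pd.testing.assert_frame_equal(out, row)

    def test_depth_one_single_read(self):
        out = rarefy(_mat([[5, 5, 5]]), depth=1, seed=1)
        assert out.to_numpy().sum() == 1
        assert (out.to_numpy() >= 0).all()

    def test_shallow_samples_dropped(self, caplog):
        m = _mat([[50, 50], [2, 1]])
        out = rarefy(m, depth=10, seed=0)
        assert list(out.index) == ["s0"]

    def test_matches_hypergeometric_mean(self):
        """Subsampling [100, 100] to depth 100 is hypergeometric: the mean of
        the first entry over many seeded draws sits within 3 SE of 50."""
        m = _mat([[100, 100]])
        draws = np.array([rarefy(m, depth=100, seed=s).iloc[0, 0]
                          for s in range(1500)])
        var = 100 * 0.5 * 0.5 * (200 - 100) / (200 - 1)   # hypergeometric variance
        se = np.sqrt(var / len(draws))
        assert abs(draws.mean() - 50.0) < 3 * se

    def test_invalid_depth(self):
        with pytest.raises(ValueError):
            rarefy(_mat([[1, 2]]), depth=0)


class TestRichnessChao1:
    @pytest.mark.parametrize("row,expect_s,expect_chao", [
        ([5, 3, 1, 1, 1, 2], 6, 6 + 9 / 2),       # classical F1^2/(2 F2)
        ([5, 3, 2, 2], 4, 4.0),                   # no singletons -> S_obs
        ([0, 0, 0], 0, 0.0),                      # empty row
        ([1, 1, 0], 2, 2 + 2 * 1 / 2),            # F2=0 -> bias-corrected form
    ])
    def test_examples(self, row, expect_s, expect_chao):
        assert richness(row) == expect_s
        assert chao1(row) == pytest.approx(expect_chao)

    @given(st.lists(st.integers(0, 10), min_size=1, max_size=40))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_chao1_never_below_richness(self, row):
        assert chao1(row) >= richness(row)

    def test_matches_reference_implementation(self, rng):
        from skbio.diversity.alpha import chao1 as skbio_chao1
        for _ in range(20):
            row = rng.integers(0, 6, size=50)
            if (row == 2).sum() > 0:
                assert chao1(row) == pytest.approx(
                    skbio_chao1(row, bias_corrected=False))


class TestAggregateTaxa:
    @pytest.fixture()
    def taxonomy(self):
        return pd.DataFrame({
            "taxon_id": ["t0", "t1", "t2"],
            "phylum": ["Acidobacteria", "Acidobacteria", "Proteobacteria"],
            "class": ["", "", "Gammaproteobacteria"],
        })

    def test_same_phylum_sums(self, taxonomy):
        out = aggregate_taxa(_mat([[3, 4, 0]]), taxonomy)
        assert out.loc["s0", "Acidobacteria"] == 7

    def test_proteobacteria_reported_at_class_rank(self, taxonomy):
        out = aggregate_taxa(_mat([[0, 0, 5]]), taxonomy)
        assert "Gammaproteobacteria" in out.columns
        assert "Proteobacteria" not in out.columns

    def test_totals_conserved(self, taxonomy, rng):
        m = _mat(rng.integers(0, 9, size=(4, 3)))
        out = aggregate_taxa(m, taxonomy)
        assert (out.sum(axis=1) == m.sum(axis=1)).all()

    def test_missing_taxonomy_raises_unless_drop(self, taxonomy):
        m = _mat([[1, 2, 3, 4]], columns=["t0", "t1", "t2", "novel"])
        with pytest.raises(KeyError):
            aggregate_taxa(m, taxonomy)
        out = aggregate_taxa(m, taxonomy, policy="drop")
        assert out.sum(axis=1).iloc[0] == 6


class TestPrevalenceFilter:
    def test_boundaries_inclusive(self):
        m = _mat(np.vstack([np.ones((8, 1)), np.zeros((2, 1))]))  # occupancy 0.8
        assert prevalence_filter(m, min_frac=0.8).shape[1] == 1
        ubiquitous = _mat(np.ones((10, 1)))
        assert prevalence_filter(ubiquitous, max_frac=0.95).shape[1] == 0

    def test_full_range_is_identity(self, rng):
        m = _mat(rng.integers(0, 3, size=(5, 8)))
        pd.testing.assert_frame_equal(prevalence_filter(m, 0.0, 1.0), m)


class TestMultidiversity:
    def test_single_component_equals_zscore(self):
        table = pd.DataFrame({"plants": [1.0, 2.0, 3.0, 4.0]})
        md = multidiversity(table).md
        z = (table["plants"] - table["plants"].mean()) / table["plants"].std(ddof=1)
        assert np.allclose(md, z)

    def test_dataset_mean_is_zero(self, rng):
        table = pd.DataFrame(rng.normal(size=(30, 5)))
        assert multidiversity(table).md.mean() == pytest.approx(0.0, abs=1e-9)

    def test_opposite_components_cancel(self):
        a = pd.Series([1.0, 2.0, 5.0, 9.0])
        table = pd.DataFrame({"up": a, "down": -2.0 * a + 7.0})
        assert np.allclose(multidiversity(table).md, 0.0)

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError):
            multidiversity(pd.DataFrame({"a": [1.0, 1.0, 1.0]}))


class TestImportanceValue:
    def test_single_species_gets_one(self):
        assert importance_value([4.0], [0.2], [1.5]) == pytest.approx([1.0])

    def test_identical_species_split_evenly(self):
        iv = importance_value([3, 3], [0.4, 0.4], [2.0, 2.0])
        assert iv == pytest.approx([0.5, 0.5])

    def test_mean_of_relative_shares(self):
        # relative shares 0.5, 0.3, 0.1 -> IV (0.5+0.3+0.1)/3 = 0.3
        iv = importance_value([5.0, 5.0], [3.0, 7.0], [1.0, 9.0])
        assert iv[0] == pytest.approx((0.5 + 0.3 + 0.1) / 3)

    @given(st.lists(st.floats(0.01, 50.0), min_size=1, max_size=8))
    @settings(deadline=None, derandomize=True, max_examples=40)
    def test_sums_to_one(self, dens):
        n = len(dens)
        iv = importance_value(dens, np.linspace(0.1, 0.9, n), np.linspace(0.5, 3, n))
        assert float(np.sum(iv)) == pytest.approx(1.0, abs=1e-9)


class TestPlantBiomass:
    def test_fir_printed_equation(self):
        # V = 100 * 10 * 0.5 = 500 -> (0.4642*500 + 47.4990)/100
        assert plant_biomass("fir", 10.0, 0.5) == pytest.approx(2.79599, abs=1e-9)

    def test_hardwood_power_law(self):
        expected = 0.6573 * 500.0 ** 1.0502 / 100.0
        assert plant_biomass("hardwood", 10.0, 0.5) == pytest.approx(expected)

    def test_tiny_herb_clipped_to_zero(self):
        # 0.0175 * 2 - 0.2888 < 0 -> clipped
        assert plant_biomass("herb", 0.02, 1.0) == 0.0

    @pytest.mark.parametrize("ptype", ["fir", "hardwood", "softwood"])
    def test_tree_biomass_monotone_in_volume(self, ptype):
        values = [plant_biomass(ptype, h, 0.6) for h in np.linspace(1, 30, 15)]
        assert all(b2 >= b1 for b1, b2 in zip(values, values[1:]))

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError):
            plant_biomass("cactus", 1.0, 0.5)
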