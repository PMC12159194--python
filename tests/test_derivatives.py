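"""Derivative formulas against brute-force oracles, correlation-map
contracts, region grouping, and the single-nucleus co-expression network."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from apaxis.derivatives import (
    Region,
    first_derivative,
    gene_pair_network,
    position_correlation,
    region_gene_groups,
    top_extremes_table,
)
from apaxis.synthetic import StripeSpec

from conftest import make_normalized


def _profiles(arr, genes=None):
    arr = np.atleast_2d(np.asarray(arr, dtype=float))
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    cols = [f"P{i}" for i in range(1, arr.shape[1] + 1)]
    return pd.DataFrame(arr, index=genes, columns=cols)


class TestFirstDerivative:
    def test_linear_profile_constant_derivative_including_terminals(self):
        prof = _profiles(2.0 * np.arange(1, 81))
        d = first_derivative(prof).to_numpy().ravel()
        assert np.allclose(d, 2.0)

    def test_three_point_toy_interior_value(self):
        d = first_derivative(_profiles([[1.0, 2.0, 4.0]])).to_numpy().ravel()
        assert d[1] == pytest.approx((4.0 - 1.0) / 2)
        assert d[0] == pytest.approx(1.0)
        assert d[2] == pytest.approx(2.0)

    def test_telescoping_identity_on_random_profiles(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, size=(50, 80))
        d = first_derivative(_profiles(x)).to_numpy()
        interior_sum = d[:, 1:-1].sum(axis=1)
        expect = 0.5 * (x[:, 79] + x[:, 78] - x[:, 0] - x[:, 1])
        assert np.allclose(interior_sum, expect, atol=1e-12)

    @settings(max_examples=25, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=5, max_size=80))
    def test_reversal_negates_interior_derivative(self, vals):
        x = np.asarray(vals)
        d = first_derivative(_profiles(x)).to_numpy().ravel()
        d_rev = first_derivative(_profiles(x[::-1])).to_numpy().ravel()
        assert np.allclose(d_rev[1:-1], -d[::-1][1:-1], atol=1e-9)

    def test_non_finite_rejected(self):
        bad = _profiles(np.array([[1.0, np.nan, 2.0]]))
        with pytest.raises(ValueError, match="non-finite"):
            first_derivative(bad)


class TestTopExtremes:
    def test_step_gene_tops_its_boundary_position(self):
        flat = np.zeros((5, 80))
        step = np.zeros(80)
        step[40:] = 10.0  # boundary between positions 40 and 41
        derivs = first_derivative(_profiles(np.vstack([flat, step])))
        table = top_extremes_table(derivs, k=1)
        top41 = table[(table["position"] == 41) & (table["side"] == "top")]
        assert list(top41["gene_id"]) == ["g5"]

    def test_k_equal_gene_count_covers_everything(self):
        rng = np.random.default_rng(0)
        derivs = _profiles(rng.normal(size=(6, 10)))
        table = top_extremes_table(derivs, k=6)
        per_pos = table.groupby(["position", "side"]).size()
        assert (per_pos == 6).all()

    def test_ties_broken_by_gene_id(self):
        derivs = _profiles(np.ones((3, 5)), genes=["zeta", "alpha", "mid"])
        table = top_extremes_table(derivs, k=3)
        first = table[(table["position"] == 1) & (table["side"] == "top")]
        assert list(first["gene_id"]) == ["alpha", "mid", "zeta"]

    def test_k_above_gene_count_rejected(self):
        with pytest.raises(ValueError):
            top_extremes_table(_profiles(np.ones((2, 5))), k=3)


class TestPositionCorrelation:
    def test_identical_columns_give_unit_correlation(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=10)
        arr = np.column_stack([base, base, rng.normal(size=10)])
        corr = position_correlation(_profiles(arr))
        assert corr.iloc[0, 1] == pytest.approx(1.0)

    def test_symmetric_unit_diagonal_bounded(self):
        rng = np.random.default_rng(2)
        corr = position_correlation(_profiles(rng.normal(size=(30, 80)))).to_numpy()
        assert np.allclose(corr, corr.T, atol=1e-12)
        assert np.allclose(np.diag(corr), 1.0)
        assert np.nanmax(np.abs(corr)) <= 1.0 + 1e-12

    def test_zero_variance_position_is_missing(self):
        rng = np.random.default_rng(3)
        arr = rng.normal(size=(10, 5))
        arr[:, 2] = 7.0
        corr = position_correlation(_profiles(arr))
        assert corr.iloc[2, :].drop(corr.columns[2]).isna().all()

    def test_fewer_than_three_genes_rejected(self):
        with pytest.raises(ValueError, match="3 genes"):
            position_correlation(_profiles(np.ones((2, 80))))

    def test_invariant_to_gene_order(self):
        rng = np.random.default_rng(4)
        prof = _profiles(rng.normal(size=(20, 80)))
        c1 = position_correlation(prof)
        c2 = position_correlation(prof.sample(frac=1.0, random_state=0))
        assert np.allclose(c1.to_numpy(), c2.to_numpy())


def _oscillatory_profiles(n_per_phase=8, period=0.125, seed=0):
    rng = np.random.default_rng(seed)
    grid = (np.arange(80) + 0.5) / 80
    rows, names = [], []
    for j, phase in enumerate((0.0, period / 2)):
        for i in range(n_per_phase):
            spec = StripeSpec(
                f"osc{j}_{i}", "oscillatory", period=period, phase=phase,
                amplitude=5.0, baseline=0.1, window=(0.55, 1.0),
            )
            rows.append(spec.mean_function(grid) + rng.normal(0, 0.05, 80))
            names.append(spec.gene_id)
    return _profiles(np.array(rows), genes=names)


class TestRegionGeneGroups:
    def test_antiphase_cohorts_separate_perfectly(self):
        prof = _oscillatory_profiles()
        derivs = first_derivative(prof)
        groups = region_gene_groups(prof, derivs, Region("C", 55, 80), n_groups=2)
        by_phase = groups.groupby(groups.index.str.slice(0, 4)).nunique()
        assert (by_phase == 1).all()  # each phase class in one group
        assert groups["osc0_0"] != groups["osc1_0"]

    def test_region_max_boundary_is_retained(self):
        grid = np.zeros((3, 80))
        grid[0, 60] = 0.2  # exactly at the threshold: kept (strict "less than")
        grid[1, 60] = 0.19  # below: excluded
        grid[2, :] = np.linspace(0, 3, 80)
        prof = _profiles(grid)
        derivs = first_derivative(_profiles(np.random.default_rng(0).normal(size=(3, 80))))
        derivs.index = prof.index
        groups = region_gene_groups(prof, derivs, Region("C", 55, 80), n_groups=2)
        assert "g0" in groups.index
        assert "g1" not in groups.index

    def test_singleton_groups_when_n_equals_genes(self):
        prof = _oscillatory_profiles(3)
        derivs = first_derivative(prof)
        groups = region_gene_groups(prof, derivs, Region("C", 55, 80), n_groups=6)
        assert groups.nunique() == 6

    def test_invalid_region_rejected(self):
        with pytest.raises(ValueError):
            Region("bad", 40, 40)
        with pytest.raises(ValueError):
            Region("bad", 0, 30)


class TestGenePairNetwork:
    def _world(self):
        rng = np.random.default_rng(5)
        n = 200
        u = np.sort(rng.uniform(0, 1, n))
        a = 2.0 + np.sin(2 * np.pi * u / 0.25)
        vals = np.vstack([
            a,
            a.copy(),                      # identical to g0
            4.0 - a,                       # antiphase to g0
            rng.normal(5, 0.1, n),         # uncorrelated
        ])
        nm, pos = make_normalized(np.clip(vals, 0, None), positions=u)
        grid = (np.arange(80) + 0.5) / 80
        return nm, pos, grid

    def test_identical_vectors_positive_unit_edge(self):
        nm, pos, grid = self._world()
        edges = gene_pair_network(nm, pos, (10, 70), ["g0", "g1", "g3"], grid)
        pair = edges[(edges["gene_a"] == "g0") & (edges["gene_b"] == "g1")]
        assert len(pair) == 1
        assert pair["r"].iloc[0] == pytest.approx(1.0)
        assert pair["sign"].iloc[0] == "positive"

    def test_antiphase_pair_negative_edge(self):
        nm, pos, grid = self._world()
        edges = gene_pair_network(nm, pos, (10, 70), ["g0", "g2", "g3"], grid)
        pair = edges[(edges["gene_a"] == "g0") & (edges["gene_b"] == "g2")]
        assert pair["sign"].tolist() == ["negative"]

    def test_exactly_ten_percent_expression_dropped(self):
        n = 100
        u = np.linspace(0, 1, n)
        vals = np.zeros((3, n))
        vals[0, :10] = 5.0           # exactly 10% of window nuclei
        vals[1, :11] = 5.0           # just above
        vals[2, :] = np.linspace(1, 2, n)
        nm, pos = make_normalized(vals, positions=u)
        grid = (np.arange(80) + 0.5) / 80
        edges = gene_pair_network(
            nm, pos, (1, 80), ["g0", "g1", "g2"], grid, min_expr_frac=0.10,
            r_threshold=-1.0,  # keep every surviving pair visible
        )
        genes_in_edges = set(edges["gene_a"]) | set(edges["gene_b"])
        assert "g0" not in genes_in_edges
        assert "g1" in genes_in_edges

    def test_too_few_window_nuclei_rejected(self):
        nm, pos, grid = self._world()
        with pytest.raises(ValueError, match="< 10"):
            gene_pair_network(nm, pos, (79, 80), ["g0", "g1"], grid)
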