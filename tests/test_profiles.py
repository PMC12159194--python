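"""Near-axis selection, terminal mirroring, and loess profile fidelity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from apaxis.profiles import (
    SmoothingParams,
    build_profile_matrix,
    mirror_positions,
    mirrored_grid,
    select_near_axis,
    smooth_profile,
)
from apaxis.synthetic import StripeSpec

from conftest import make_normalized


def _pos_table(positions, distances=None):
    positions = np.asarray(positions, dtype=float)
    df = pd.DataFrame(
        {
            "nucleus_id": [f"n{i}" for i in range(len(positions))],
            "position": positions,
            "distance": 0.0 if distances is None else np.asarray(distances, dtype=float),
            "on_extension": False,
        }
    )
    return df


class TestSelectNearAxis:
    def test_boundary_is_inclusive(self):
        pos = _pos_table([0.1, 0.2, 0.3], distances=[0.1, 0.3, 0.31])
        out = select_near_axis(pos, 0.3)
        assert list(out["nucleus_id"]) == ["n0", "n1"]

    def test_infinite_threshold_is_identity(self):
        pos = _pos_table([0.1, 0.2], distances=[5.0, 9.0])
        assert len(select_near_axis(pos, np.inf)) == 2

    def test_zero_threshold_keeps_only_on_curve(self):
        pos = _pos_table([0.1, 0.2, 0.5], distances=[0.0, 1e-9, 0.0])
        assert list(select_near_axis(pos, 0.0)["nucleus_id"]) == ["n0", "n2"]

    def test_empty_result_rejected(self):
        pos = _pos_table([0.1], distances=[2.0])
        with pytest.raises(ValueError, match="no nuclei"):
            select_near_axis(pos, 0.5)


class TestMirrorPositions:
    def test_doubles_rows_and_fixes_terminus(self):
        pos = _pos_table([1.0, 1.5, 2.8, 3.0])
        out = mirror_positions(pos, a=1.0, b=3.0)
        assert len(out) == 8
        # nucleus at p = a mirrors onto itself
        n0 = out[out["nucleus_id"] == "n0"]["position"]
        assert set(n0) == {1.0}
        # anterior-half nucleus reflects below a, posterior-half above b
        assert 2 * 1.0 - 1.5 in set(out[out["nucleus_id"] == "n1"]["position"])
        assert 2 * 3.0 - 2.8 in set(out[out["nucleus_id"] == "n2"]["position"])

    def test_midpoint_goes_to_anterior_half(self):
        pos = _pos_table([2.0])
        out = mirror_positions(pos, a=1.0, b=3.0)
        assert set(out["position"]) == {2.0, 0.0}  # reflected at a, not b

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_mirror_range_and_multiset_property(self, raw):
        a, b = 0.0, 1.0
        pos = _pos_table(raw)
        out = mirror_positions(pos, a, b)
        assert len(out) == 2 * len(raw)
        c = 0.5 * (a + b)
        lo, hi = 2 * a - c, 2 * b - c
        assert out["position"].between(lo, hi).all()
        # symmetric input -> output multiset symmetric about c
        sym = np.concatenate([np.asarray(raw), 2 * c - np.asarray(raw)])
        out_sym = mirror_positions(_pos_table(sym), a, b)["position"].to_numpy()
        assert np.allclose(
            np.sort(out_sym), np.sort(2 * c - out_sym), atol=1e-12
        )


class TestSmoothProfile:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.u = np.sort(rng.uniform(0, 1, 1200))
        self.params = SmoothingParams()

    def _doubled(self, y):
        pos = _pos_table(self.u)
        doubled = mirror_positions(pos, 0.0, 1.0)
        dpos = doubled["position"].to_numpy() + 1e-10 * np.arange(2 * len(self.u))
        return dpos, np.concatenate([y, y])

    def test_constant_expression_gives_constant_profile(self):
        dpos, dy = self._doubled(np.full_like(self.u, 3.7))
        prof = smooth_profile(dpos, dy, self.params, 0.0, 1.0)
        assert prof.shape == (80,)
        assert np.allclose(prof, 3.7, atol=1e-8)

    def test_linear_expression_recovered_within_one_percent(self):
        y = 2.0 + 3.0 * self.u
        dpos = np.concatenate([self.u, np.where(self.u <= 0.5, -self.u, 2 - self.u)])
        dy = np.concatenate([y, y])
        prof = smooth_profile(
            dpos + 1e-10 * np.arange(len(dpos)), dy, self.params, 0.0, 1.0
        )
        grid = mirrored_grid(0.0, 1.0, self.params)[40:120]
        expect = 2.0 + 3.0 * grid
        # mirroring folds the line near the termini; check the interior
        assert np.abs(prof[5:-5] - expect[5:-5]).max() < 0.01 * np.ptp(y)

    def test_bi_split_peaks_within_two_subdivisions(self):
        spec = StripeSpec(
            "g", "bi_split", peak_centers=(0.15, 0.25), peak_width=0.03,
            amplitude=5.0, baseline=0.1,
        )
        dpos, dy = self._doubled(spec.mean_function(self.u))
        prof = smooth_profile(dpos, dy, self.params, 0.0, 1.0)
        peaks = [
            i + 1
            for i in range(1, 79)
            if prof[i] > prof[i - 1] and prof[i] >= prof[i + 1]
            and prof[i] > 0.3 * prof.max()
        ]
        assert len(peaks) == 2
        assert abs(peaks[0] - 0.15 * 80) <= 2
        assert abs(peaks[1] - 0.25 * 80) <= 2

    def test_even_function_has_zero_terminal_slope(self):
        # cos(2 pi u) is even about both termini; after mirroring + smoothing
        # the estimated slope at each terminus must vanish
        y = np.cos(2 * np.pi * self.u)
        dpos, dy = self._doubled_mirrored(y)
        prof = smooth_profile(dpos, dy, self.params, 0.0, 1.0)
        interior_slope = np.abs(np.diff(prof)).max()
        assert abs(prof[1] - prof[0]) < 0.1 * interior_slope
        assert abs(prof[79] - prof[78]) < 0.1 * interior_slope

    def _doubled_mirrored(self, y):
        pos = _pos_table(self.u)
        doubled = mirror_positions(pos, 0.0, 1.0)
        order = doubled.index.to_numpy()
        dy = np.concatenate([y, y])
        dpos = doubled["position"].to_numpy() + 1e-10 * np.arange(len(order))
        return dpos, dy

    def test_degenerate_positions_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            smooth_profile(np.full(100, 0.5), np.ones(100), self.params, 0.0, 1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            smooth_profile(np.linspace(0, 1, 10), np.ones(10), self.params, 0.0, 1.0)


class TestBuildProfileMatrix:
    def _world(self, n=800, seed=0):
        rng = np.random.default_rng(seed)
        u = rng.uniform(0, 1, n)
        osc_a = StripeSpec("oscA", "oscillatory", period=0.125, phase=0.0,
                           amplitude=5.0, baseline=0.1, window=(0.5, 1.0))
        osc_b = StripeSpec("oscB", "oscillatory", period=0.125, phase=0.0625,
                           amplitude=5.0, baseline=0.1, window=(0.5, 1.0))
        vals = np.vstack(
            [
                osc_a.mean_function(u),
                osc_b.mean_function(u),
                np.zeros(n),
                np.full(n, 2.0),
            ]
        )
        nm, pos = make_normalized(vals, positions=u)
        return nm, pos

    def test_zero_gene_zero_profile_and_completeness(self):
        nm, pos = self._world()
        prof = build_profile_matrix(nm, pos)
        assert len(prof) == len(nm.genes)
        assert np.allclose(prof.loc["g2"], 0.0)
        assert np.allclose(prof.loc["g3"], 2.0, atol=1e-8)

    def test_antiphase_pair_negatively_correlated_in_posterior(self):
        nm, pos = self._world()
        prof = build_profile_matrix(nm, pos)
        post = [f"P{i}" for i in range(45, 81)]
        r = np.corrcoef(prof.loc["g0", post], prof.loc["g1", post])[0, 1]
        assert r < 0

    def test_invariant_to_nucleus_order(self):
        nm, pos = self._world()
        prof1 = build_profile_matrix(nm, pos)
        perm = np.random.default_rng(1).permutation(len(pos))
        pos2 = pos.iloc[perm].reset_index(drop=True)
        pos2.attrs.update(pos.attrs)
        prof2 = build_profile_matrix(nm, pos2)
        assert np.allclose(prof1.to_numpy(), prof2.to_numpy(), atol=1e-6)

    def test_unknown_nuclei_rejected(self):
        nm, pos = self._world(100)
        bad = pos.copy()
        bad.loc[0, "nucleus_id"] = "missing"
        bad.attrs.update(pos.attrs)
        with pytest.raises(ValueError, match="missing"):
            build_profile_matrix(nm, bad)
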