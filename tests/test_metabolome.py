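"""Charge ratios, normalisation, classical MDS and relaxation metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hs
from scipy.spatial.distance import pdist, squareform

from sretools import (
    MetabolitePanel,
    axp_normalize,
    classical_mds,
    distance_matrix,
    energy_charge,
    minmax_normalize,
    reduction_charges,
    relaxation_metrics,
)

pool = hs.floats(min_value=0.0, max_value=100.0, allow_nan=False)


class TestEnergyCharge:
    @pytest.mark.parametrize("atp,adp,amp,expected", [
        (1.0, 0.0, 0.0, 1.0),
        (0.0, 0.0, 1.0, 0.0),
        (1.0, 1.0, 1.0, 0.5),
        (0.0, 1.0, 0.0, 0.5),
    ])
    def test_boundary_cases(self, atp, adp, amp, expected):
        assert energy_charge(atp, adp, amp) == pytest.approx(expected, abs=1e-15)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            energy_charge(0.0, 0.0, 0.0)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(atp=pool, adp=pool, amp=pool, scale=hs.floats(0.1, 10.0))
    def test_scale_invariance_and_bounds(self, atp, adp, amp, scale):
        if atp + adp + amp == 0:
            return
        aec = energy_charge(atp, adp, amp)
        assert 0.0 <= aec <= 1.0
        assert energy_charge(scale * atp, scale * adp, scale * amp) == pytest.approx(
            aec, rel=1e-9)

    def test_monotone_in_atp_and_amp_at_fixed_total(self):
        base = energy_charge(1.0, 1.0, 1.0)
        assert energy_charge(1.5, 1.0, 0.5) > base       # ATP replacing AMP
        assert energy_charge(0.5, 1.0, 1.5) < base


class TestReductionCharges:
    def test_printed_anabolic_ratio_implies_charge(self):
        """NADPH/NADP+ = 1.28 -> anabolic charge 1.28/2.28 = 0.561."""
        total = 0.36
        nadph = total * 1.28 / 2.28
        cs = reduction_charges(0.17, 3.53, nadph, total - nadph)
        assert cs.anabolic_charge == pytest.approx(0.561, abs=0.001)
        assert cs.nadph_nadp_ratio == pytest.approx(1.28, abs=0.01)
        assert cs.anabolic_total == pytest.approx(0.36, abs=1e-12)

    def test_catabolic_charge_inversion(self):
        """NADH = 0.17 with charge 0.046 implies NAD+ ~ 3.53."""
        nad = 0.17 / 0.046 - 0.17
        assert nad == pytest.approx(3.53, abs=0.01)
        cs = reduction_charges(0.17, nad, 0.2, 0.16)
        assert cs.catabolic_charge == pytest.approx(0.046, abs=1e-12)

    def test_balanced_couples_sit_at_half(self):
        cs = reduction_charges(1.0, 1.0, 0.4, 0.4)
        assert cs.catabolic_charge == 0.5
        assert cs.anabolic_charge == 0.5

    def test_empty_couple_rejected(self):
        with pytest.raises(ValueError):
            reduction_charges(0.0, 0.0, 0.2, 0.2)

    def test_delta_method_sd_positive_and_scales(self):
        cs = reduction_charges(0.17, 3.53, 0.20, 0.16,
                               sds=(0.03, 0.1, 0.01, 0.01))
        assert cs.catabolic_charge_sd > 0
        assert cs.anabolic_charge_sd > 0


class TestAxpNormalize:
    def test_default_factors(self):
        out = axp_normalize({"ATP": 1.0, "ADP": 1.0, "AMP": 1.0})
        assert out == {"ATP": 2.71, "ADP": 1.88, "AMP": 1.21}

    def test_override_to_identity(self):
        out = axp_normalize({"ATP": 3.3}, factors={"ATP": 1.0})
        assert out["ATP"] == 3.3

    def test_linearity(self):
        a = axp_normalize({"ATP": np.array([1.0, 2.0])})
        b = axp_normalize({"ATP": np.array([2.0, 4.0])})
        np.testing.assert_allclose(2 * a["ATP"], b["ATP"])

    def test_unknown_species_rejected(self):
        with pytest.raises(KeyError, match="GTP"):
            axp_normalize({"GTP": 1.0})


class TestNormalisationAndDistances:
    def test_minmax_column_example(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        out = minmax_normalize(m)
        np.testing.assert_allclose(out["a"], [0.0, 0.5, 1.0])
        np.testing.assert_allclose(out["b"], 0.0)   # constant-column convention

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(hs.lists(hs.floats(-50, 50, allow_nan=False).map(lambda v: round(v, 3)),
                    min_size=3, max_size=8),
           hs.floats(0.1, 5.0), hs.floats(-10, 10))
    def test_affine_invariance_and_bounds(self, col, a, b):
        m = pd.DataFrame({"x": col})
        out = minmax_normalize(m)
        assert ((out["x"] >= 0) & (out["x"] <= 1)).all()
        out2 = minmax_normalize(m * a + b)
        np.testing.assert_allclose(out2["x"], out["x"], atol=1e-6)

    def test_minmax_idempotent_on_full_range_columns(self):
        m = pd.DataFrame({"x": [0.0, 0.25, 1.0]})
        out = minmax_normalize(minmax_normalize(m))
        np.testing.assert_allclose(out["x"], [0.0, 0.25, 1.0])

    def test_three_four_five_distance(self):
        m = pd.DataFrame([[0.0, 0.0], [3.0, 4.0]])
        d = distance_matrix(m)
        assert d.iloc[0, 1] == pytest.approx(5.0)
        assert d.iloc[0, 0] == 0.0

    def test_triangle_inequality_on_random_matrices(self):
        rng = np.random.default_rng(11)
        m = pd.DataFrame(rng.normal(size=(6, 4)))
        d = distance_matrix(m).to_numpy()
        n = d.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_nan_requires_pairwise_option(self):
        m = pd.DataFrame([[0.0, np.nan], [1.0, 2.0]])
        with pytest.raises(ValueError):
            distance_matrix(m)
        d = distance_matrix(m, pairwise_complete=True)
        assert np.isfinite(d.to_numpy()).all()


class TestClassicalMDS:
    def test_two_points_embed_at_plus_minus_half_distance(self):
        with pytest.warns(RuntimeWarning):
            res = classical_mds(np.array([[0.0, 6.0], [6.0, 0.0]]), k=2)
        np.testing.assert_allclose(sorted(res.coordinates["dim1"]), [-3.0, 3.0])

    def test_planar_configuration_distances_reproduced(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(7, 2))
        D = squareform(pdist(pts))
        res = classical_mds(pd.DataFrame(D), k=2)
        D2 = squareform(pdist(res.coordinates.to_numpy()))
        np.testing.assert_allclose(D2, D, atol=1e-8)

    def test_agrees_with_independent_ordination_oracle(self):
        """Coordinates match scikit-bio's principal-coordinate analysis."""
        from skbio import DistanceMatrix
        from skbio.stats.ordination import pcoa

        rng = np.random.default_rng(0)
        pts = rng.normal(size=(6, 3))
        D = squareform(pdist(pts))
        mine = classical_mds(pd.DataFrame(D), k=3)
        ref = pcoa(DistanceMatrix(D), method="eigh")
        np.testing.assert_allclose(mine.eigenvalues[:3],
                                   ref.eigvals.to_numpy()[:3], atol=1e-8)
        for j in range(3):
            a = mine.coordinates.to_numpy()[:, j]
            b = ref.samples.to_numpy()[:, j]
            sign = np.sign(a @ b) or 1.0
            np.testing.assert_allclose(a, sign * b, atol=1e-8)

    def test_axis_signs_fixed_deterministically(self):
        D = squareform(pdist(np.array([[0.0, 0], [1, 0], [0, 2], [3, 3]])))
        res = classical_mds(D, k=2)
        for j in range(2):
            col = res.coordinates.to_numpy()[:, j]
            nz = col[np.abs(col) > 1e-12]
            assert nz[0] > 0

    def test_centered_coordinates_and_sorted_eigenvalues(self):
        rng = np.random.default_rng(5)
        D = squareform(pdist(rng.normal(size=(5, 4))))
        res = classical_mds(D, k=2)
        np.testing.assert_allclose(res.coordinates.mean(axis=0), 0.0, atol=1e-10)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            classical_mds(np.ones((2, 3)))
        with pytest.raises(ValueError):
            classical_mds(np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestRelaxation:
    def spiral_mds(self):
        theta = np.linspace(0, 3 * np.pi, 12)
        r = np.exp(-theta / 4.0)
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        pts = np.vstack([pts, [0.0, 0.0]])          # attractor at origin
        labels = [f"t{i}" for i in range(12)] + ["att"]
        D = pd.DataFrame(squareform(pdist(pts)), index=labels, columns=labels)
        return classical_mds(D, k=2)

    def test_identical_anchors_give_identical_distances(self):
        mds = self.spiral_mds()
        res = relaxation_metrics(mds, "t0", "t0")
        np.testing.assert_allclose(res.distances["to_reference"],
                                   res.distances["to_attractor"])

    def test_converging_spiral_flags_monotone_convergence(self):
        mds = self.spiral_mds()
        res = relaxation_metrics(mds, "t0", "att", tail=5)
        d = res.distances["to_attractor"].to_numpy()[:-1]
        assert np.all(np.diff(d[-5:]) <= 1e-9)
        assert res.monotone_convergence

    def test_closed_loop_returns_to_start_without_convergence(self):
        theta = np.linspace(0, 2 * np.pi, 13)
        pts = np.column_stack([np.cos(theta), np.sin(theta)])
        labels = list(range(13))
        D = pd.DataFrame(squareform(pdist(pts)), index=labels, columns=labels)
        mds = classical_mds(D, k=2)
        res = relaxation_metrics(mds, 0, 6, tail=4)
        assert res.distances["to_reference"].iloc[-1] == pytest.approx(0.0, abs=1e-9)
        assert not res.monotone_convergence

    def test_missing_label_rejected(self):
        mds = self.spiral_mds()
        with pytest.raises(KeyError):
            relaxation_metrics(mds, "t0", "nope")


class TestPanel:
    def tidy(self):
        rows = []
        for t in (0.0, 2.0, 9.0):
            for m, base in (("ATP", 8.0), ("ADP", 1.0)):
                for rep in (1, 2, 3):
                    rows.append((t, m, rep, base + 0.1 * rep))
        return pd.DataFrame(rows, columns=["sample_time_min", "metabolite",
                                           "replicate", "value_umol_gDMB"])

    def test_mean_matrix_averages_replicates(self):
        panel = MetabolitePanel(self.tidy())
        m = panel.mean_matrix()
        assert m.loc[0.0, "ATP"] == pytest.approx(8.2)
        assert list(m.index) == [0.0, 2.0, 9.0]

    def test_include_list_orders_and_validates(self):
        panel = MetabolitePanel(self.tidy())
        m = panel.mean_matrix(include=["ADP", "ATP"])
        assert list(m.columns) == ["ADP", "ATP"]
        with pytest.raises(KeyError):
            panel.mean_matrix(include=["XYZ"])

    def test_negative_values_and_duplicates_rejected(self):
        bad = self.tidy()
        bad.loc[0, "value_umol_gDMB"] = -1.0
        with pytest.raises(ValueError):
            MetabolitePanel(bad)
        dup = pd.concat([self.tidy(), self.tidy().iloc[[0]]])
        with pytest.raises(ValueError):
            MetabolitePanel(dup)
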