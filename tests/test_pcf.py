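"""Cross-pair correlation function, bootstrap CI and topographical map."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from spatcell import (
    CellPattern,
    PCFParams,
    PairedAttraction,
    SimSpec,
    Window,
    cross_pcf,
    pool_pcf,
    simulate,
    simulate_csr,
    tcm,
)
from spatcell.geometry import annulus_window_area


def brute_force_g(pattern, type_a, type_b, radii, dr):
    """Independent O(N_A·N_B) pair-distance binning of the same estimator."""
    A, B = pattern.points(type_a), pattern.points(type_b)
    w, h = pattern.window.width, pattern.window.height
    lam_b = len(B) / pattern.window.area
    g = []
    for r in radii:
        total = 0.0
        for i, a in enumerate(A):
            d = np.hypot(B[:, 0] - a[0], B[:, 1] - a[1])
            if type_a == type_b:
                d = np.delete(d, i)
            count = int(((d >= r) & (d < r + dr)).sum())
            W = float(annulus_window_area(a[0], a[1], r, r + dr, w, h))
            total += count / W
        g.append(total / (len(A) * lam_b))
    return np.array(g)


class TestCrossPCF:
    def test_analytic_paired_value(self, paired_pattern):
        res = cross_pcf(paired_pattern, "A", "B", PCFParams(n_boot=100, seed=1))
        target = 1e6 / (50 * np.pi * 500.0)  # |Ω| / (N_B · π(30²−20²))
        assert res.at(20.0) == pytest.approx(target, rel=1e-2)

    def test_matches_brute_force_oracle_exactly(self, csr_pattern):
        params = PCFParams(curve_radii=(0.0, 10.0, 20.0, 45.0, 120.0), n_boot=0)
        res = cross_pcf(csr_pattern, "A", "B", params)
        oracle = brute_force_g(csr_pattern, "A", "B", np.array(params.curve_radii), 10.0)
        assert np.allclose(res.g[np.isin(res.radii, params.curve_radii)], oracle, rtol=1e-10)

    def test_self_pairs_excluded_for_same_type(self, csr_pattern):
        params = PCFParams(curve_radii=(0.0, 20.0), n_boot=0)
        res = cross_pcf(csr_pattern, "A", "A", params)
        oracle = brute_force_g(csr_pattern, "A", "A", np.array([0.0, 20.0]), 10.0)
        assert np.allclose(res.g[[0, 1]], oracle)

    def test_csr_ci_covers_one(self, csr_pattern):
        res = cross_pcf(csr_pattern, "A", "B", PCFParams(n_boot=500, seed=2))
        lo, hi = res.ci_at(20.0)
        assert lo <= 1.0 <= hi
        assert lo <= res.at(20.0) <= hi

    def test_absent_type_flagged_undefined(self, csr_pattern):
        res = cross_pcf(csr_pattern, "A", "Z", PCFParams(n_boot=10))
        assert not res.defined and np.all(np.isnan(res.g))

    def test_displaced_pairs_peak_at_offset(self, window):
        st = PairedAttraction("A", "B", 50.0, n_pairs=40, margin=100.0, min_separation=81.0)
        p = simulate(SimSpec(window, structure=st, seed=9))
        res = cross_pcf(p, "A", "B", PCFParams(n_boot=0))
        assert res.at(20.0) == pytest.approx(0.0, abs=1e-12)
        assert res.r_at_g_max in (45.0, 50.0)  # annuli [45,55) and [50,60) hold d=50

    def test_zero_width_ci_when_contributions_identical(self, paired_pattern):
        # every anchor holds exactly one partner in [20,30) and W_a is unclipped
        res = cross_pcf(paired_pattern, "A", "B", PCFParams(n_boot=200, seed=3))
        lo, hi = res.ci_at(20.0)
        assert lo == pytest.approx(hi)
        assert lo == pytest.approx(res.at(20.0))

    def test_single_anchor_ci_undefined(self, window):
        cells = pd.DataFrame(
            {"cell_id": [1, 2], "x": [500.0, 520.0], "y": [500.0, 500.0],
             "cell_type": ["A", "B"]}
        )
        p = CellPattern("r", "c", window, cells)
        res = cross_pcf(p, "A", "B", PCFParams(n_boot=100))
        assert res.defined and not res.ci_defined

    def test_ci_width_shrinks_with_anchor_count(self, window):
        widths = []
        for n, lam in [(50, 5e-5), (200, 2e-4), (800, 8e-4)]:
            p = simulate_csr(SimSpec(window, intensity={"A": lam, "B": 3e-4}, seed=n))
            res = cross_pcf(p, "A", "B", PCFParams(curve_radii=(20.0,), n_boot=300, seed=4))
            lo, hi = res.ci_at(20.0)
            widths.append(hi - lo)
        # ~1/sqrt(N_A): each 4x step shrinks width by ~2, allow generous slack
        assert widths[0] > widths[1] > widths[2]
        assert widths[0] / widths[2] == pytest.approx(4.0, rel=0.6)

    def test_nested_annuli_counts_add(self, csr_pattern):
        wide = cross_pcf(csr_pattern, "A", "B", PCFParams(curve_radii=(20.0,), annulus_width=10.0, n_boot=0))
        half1 = cross_pcf(csr_pattern, "A", "B", PCFParams(curve_radii=(20.0,), annulus_width=5.0, n_boot=0))
        half2 = cross_pcf(csr_pattern, "A", "B", PCFParams(curve_radii=(25.0,), annulus_width=5.0, n_boot=0))
        i20 = list(wide.radii).index(20.0)
        assert wide.observed[i20] == half1.observed[list(half1.radii).index(20.0)] + half2.observed[
            list(half2.radii).index(25.0)
        ]


class TestPooling:
    def test_pooled_equals_single_roi(self, csr_pattern):
        single = cross_pcf(csr_pattern, "A", "B", PCFParams(n_boot=100, seed=5))
        pooled = pool_pcf([single])
        assert np.allclose(pooled.g, single.g)

    def test_two_identical_rois_pool_to_same_curve(self, csr_pattern):
        r1 = cross_pcf(csr_pattern, "A", "B", PCFParams(n_boot=50, seed=6))
        pooled = pool_pcf([r1, r1])
        assert np.allclose(pooled.g, r1.g)
        assert pooled.n_a == 2 * r1.n_a


class TestTCM:
    def test_isolated_anchor_gamma_is_minus_one(self, window):
        cells = pd.DataFrame(
            {
                "cell_id": [1, 2],
                "x": [200.0, 800.0],
                "y": [200.0, 800.0],
                "cell_type": ["A", "B"],
            }
        )
        p = CellPattern("r", "c", window, cells)
        field = tcm(p, "A", "B", threshold=100.0)
        assert field.cells["gamma"].iloc[0] == pytest.approx(-1.0)

    def test_enrichment_sign_per_anchor(self, window):
        rng = np.random.default_rng(12)
        ax = rng.uniform(150, 850, 20)
        ay = rng.uniform(150, 850, 20)
        # B coincident with the first 10 anchors only
        cells = pd.DataFrame(
            {
                "cell_id": np.arange(1, 31),
                "x": np.concatenate([ax, ax[:10]]),
                "y": np.concatenate([ay, ay[:10]]),
                "cell_type": ["A"] * 20 + ["B"] * 10,
            }
        )
        p = CellPattern("r", "c", window, cells)
        field = tcm(p, "A", "B", threshold=100.0)
        gam = field.cells["gamma"].to_numpy()
        assert np.all(gam[:10] > 0)

    def test_observed_matches_cross_k_numerator(self, csr_pattern):
        threshold = 100.0
        field = tcm(csr_pattern, "A", "B", threshold=threshold)
        A, B = csr_pattern.points("A"), csr_pattern.points("B")
        k_numerator = int((cdist(A, B) < threshold).sum())
        assert int(field.cells["observed"].sum()) == k_numerator

    def test_smoothed_grid_shape(self, csr_pattern):
        field = tcm(csr_pattern, "A", "B", threshold=100.0, grid_spacing=50.0)
        assert field.grid.shape == (20, 20)
        assert np.all(np.isfinite(field.grid))
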