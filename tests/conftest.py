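import numpy as np
import pytest

from spatcell import (
    CSR,
    PairedAttraction,
    SimSpec,
    TripletClusters,
    Window,
    simulate,
    simulate_csr,
)


@pytest.fixture
def window() -> Window:
    return Window(1000.0, 1000.0)


@pytest.fixture
def csr_pattern(window):
    """Two independent CSR types, ~300 cells each."""
    spec = SimSpec(window, intensity={"A": 3e-4, "B": 3e-4}, seed=11)
    return simulate_csr(spec)


@pytest.fixture
def paired_pattern(window):
    """Closed-form cross-PCF construction: 50 isolated A–B pairs, 25 µm apart."""
    spec = SimSpec(
        window,
        structure=PairedAttraction("A", "B", 25.0, n_pairs=50, margin=100.0, min_separation=56.0),
        seed=7,
    )
    return simulate(spec)


@pytest.fixture
def triplet_pattern(window):
    """30 tight three-type clusters of radius 5 µm, no background."""
    spec = SimSpec(window, structure=TripletClusters("A", "B", "C", 30, 5.0), seed=13)
    return simulate(spec)


def brute_force_mec_radius(pts) -> float:
    """Independent minimal-enclosing-circle oracle.

    Minimises the covering radius f(c) = max_i |c − p_i| (convex) by
    Nelder–Mead from several starts; any covering radius is an upper bound,
    and the polish from multiple starts converges to the optimum.
    """
    from scipy.optimize import minimize

    pts = np.asarray(pts, dtype=float)

    def covering(c):
        return np.max(np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1]))

    starts = [pts.mean(axis=0)] + [
        0.5 * (pts[i] + pts[j]) for i in range(3) for j in range(i + 1, 3)
    ]
    best = np.inf
    for s in starts:
        res = minimize(
            covering, s, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
        )
        best = min(best, covering(res.x))
    return float(best)
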