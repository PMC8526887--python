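import numpy as np
import pytest

import sparsemet as sm


@pytest.fixture(scope="session")
def small_wheat():
    """A small wheat-like dataset shared by read-only tests."""
    spec = sm.wheat_like_spec(n_lines=60, n_markers=600, n_families=5, seed=11)
    geno, truth, blues = sm.simulate_dataset(spec)
    G = sm.vanraden_grm(geno)
    return spec, geno, truth, blues, G


@pytest.fixture()
def toy_geno():
    """Six lines, five markers, printed dosages (one marker monomorphic,
    one with missing calls)."""
    dos = np.array(
        [
            [0, 2, 1, 0, 0],
            [2, 2, 0, 0, 2],
            [0, 2, 2, 0, np.nan],
            [2, 2, 1, 0, np.nan],
            [0, 2, 0, 0, 2],
            [2, 2, 2, 0, np.nan],
        ],
        dtype=float,
    )
    return sm.GenotypeMatrix(
        [f"L{i}" for i in range(1, 7)], [f"M{j}" for j in range(1, 6)], dos
    )


def marginal_covariance(blues, G, varcomps, E=None):
    """Marginal covariance of the observed cells under the GxE model."""
    li, ei, y = blues.observed_cells()
    K_g = G[np.ix_(li, li)]
    if E is None:
        K_v = (ei[:, None] == ei[None, :]).astype(float)
    else:
        K_v = E[np.ix_(ei, ei)]
    V = (
        varcomps["sigma_v2"] * K_v
        + varcomps["sigma_g2"] * K_g
        + varcomps["sigma_gv2"] * (K_g * K_v)
        + varcomps["sigma_e2"] * np.eye(y.size)
    )
    return li, ei, y, V


def gls_blups(blues, G, varcomps, E=None):
    """Independent GLS/BLUP oracle on the marginal model.

    Returns (mu, g_hat, pev_g) computed without the mixed-model equations:
    mu by generalized least squares, g_hat = sg2 G Zg' V^-1 (y - mu), and
    PEV = G sg2 - sg2^2 G Zg' P Zg G with P the GLS projection.
    """
    li, ei, y, V = marginal_covariance(blues, G, varcomps, E)
    N = y.size
    n = blues.n_lines
    X = np.ones((N, 1))
    Vinv = np.linalg.inv(V)
    XtVX = X.T @ Vinv @ X
    mu = float(np.linalg.solve(XtVX, X.T @ Vinv @ y).item())
    P = Vinv - Vinv @ X @ np.linalg.solve(XtVX, X.T @ Vinv)
    Zg = np.zeros((N, n))
    Zg[np.arange(N), li] = 1.0
    sg2 = varcomps["sigma_g2"]
    g_hat = sg2 * G @ Zg.T @ Vinv @ (y - mu)
    var_ghat = sg2**2 * G @ Zg.T @ P @ Zg @ G
    pev = sg2 * G - var_ghat
    return mu, g_hat, pev
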