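"""Simulated response to selection from the fitted genomic model.

Selection acts on the BLUP g_hat while the realised gain is the mean true
genetic main effect g of the selected lines. Under the mixed model the joint
distribution of (g, g_hat) is multivariate normal with covariance

    Omega = [[ G sg2,        G sg2 - PEV ],
             [ G sg2 - PEV,  G sg2 - PEV ]]

where PEV = C^gg * se2 is the prediction error variance block from the
inverted mixed-model equations (standard BLUP identities: var(g_hat) =
cov(g, g_hat) = var(g) - PEV). Draws w = Gamma z with Gamma Gamma' = Omega
and z standard normal reproduce this joint distribution exactly, so the
response at a selection ratio p is estimated as the Monte-Carlo average of
the mean true g over the ceil(p n) lines with the largest simulated g_hat.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import lapack

from .met import MetFit

__all__ = [
    "OmegaFactor",
    "ResponseCurve",
    "build_omega",
    "factor_omega",
    "simulate_response",
    "sample_covariance_check",
    "DEFAULT_RATIOS",
]

DEFAULT_RATIOS = tuple(np.round(np.arange(0.1, 0.91, 0.1), 2))


@dataclass
class OmegaFactor:
    """Covariance of (g, g_hat) and a factor Gamma with Gamma Gamma' = Omega."""

    n: int
    omega: np.ndarray
    gamma: np.ndarray | None = None
    eigenvalues: np.ndarray | None = None
    n_clipped: int = 0
    clip_magnitude: float = 0.0
    method: str = "eigen"

    def reconstruction_error(self) -> float:
        """Relative Frobenius error of Gamma Gamma' against Omega."""
        if self.gamma is None:
            raise ValueError("factorization not computed")
        num = np.linalg.norm(self.gamma @ self.gamma.T - self.omega, "fro")
        den = max(np.linalg.norm(self.omega, "fro"), 1e-300)
        return float(num / den)


@dataclass
class ResponseCurve:
    """Achieved response to selection per selection ratio."""

    scenario_id: str
    ratios: np.ndarray
    responses: np.ndarray
    n_runs: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scenario_id": self.scenario_id,
                "ratio": self.ratios,
                "response": self.responses,
                "n_runs": self.n_runs,
                "seed": self.seed,
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_omega(fit: MetFit, tol: float = 1e-6) -> OmegaFactor:
    """Assemble Omega = var(g, g_hat) from a fitted model.

    var(g) = G sg2; var(g_hat) = cov(g, g_hat) = G sg2 - PEV with
    PEV = C^gg se2. Raises if the PEV block exceeds G sg2 beyond tolerance
    (that signals broken mixed-model equations upstream).
    """
    n = fit.n_lines
    sg2 = fit.varcomps["sigma_g2"]
    var_g = fit.G * sg2
    pev = fit.pev_g()
    var_ghat = var_g - pev
    scale = max(float(np.abs(var_g).max()), 1e-300)
    w = np.linalg.eigvalsh(0.5 * (var_ghat + var_ghat.T))
    if w.min() < -tol * scale:
        raise ValueError(
            "PEV block exceeds G*sigma_g2 beyond tolerance: "
            f"min eigenvalue of var(g_hat) = {w.min():.3e} (scale {scale:.3e})"
        )
    omega = np.block([[var_g, var_ghat], [var_ghat, var_ghat]])
    omega = 0.5 * (omega + omega.T)
    return OmegaFactor(n=n, omega=omega)


def factor_omega(
    omega: np.ndarray | OmegaFactor,
    method: str = "eigen",
    clip_tol: float = 1e-6,
) -> OmegaFactor:
    """Factor Omega as Gamma Gamma'.

    method="eigen": eigendecompose Omega = D Lambda D' and set
    Gamma = D Lambda^{1/2}; eigenvalues within -clip_tol * max(Lambda) of
    zero are clipped to 0 (counted and reported), more negative ones raise.
    The default tolerance matches the diagonal ridge used when inverting
    covariance blocks upstream, which perturbs Omega at that relative scale.
    method="pivoted-cholesky": LAPACK dpstrf Cholesky with complete
    pivoting, an independent factorization used for cross-checking.
    """
    if isinstance(omega, OmegaFactor):
        of = omega
        A = of.omega
    else:
        A = np.asarray(omega, float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("Omega must be square")
        if A.shape[0] % 2 != 0:
            raise ValueError("Omega must be 2n x 2n")
        of = OmegaFactor(n=A.shape[0] // 2, omega=A)
    if not np.allclose(A, A.T, atol=1e-8 * max(1.0, float(np.abs(A).max()))):
        raise ValueError("Omega must be symmetric")
    A = 0.5 * (A + A.T)
    if method == "eigen":
        w, D = np.linalg.eigh(A)
        wmax = max(float(w.max()), 0.0)
        neg = w < 0
        if wmax > 0 and w.min() < -clip_tol * wmax:
            raise ValueError(
                f"Omega has a substantially negative eigenvalue ({w.min():.3e}); "
                "non-PSD Omega signals an upstream bug"
            )
        of.n_clipped = int(neg.sum())
        of.clip_magnitude = float(-w[neg].sum()) if neg.any() else 0.0
        wc = np.clip(w, 0.0, None)
        of.gamma = D * np.sqrt(wc)
        of.eigenvalues = w
    elif method == "pivoted-cholesky":
        c, piv, rank, info = lapack.dpstrf(A, lower=1)
        if info < 0:
            raise ValueError("pivoted Cholesky failed")
        L = np.tril(c)
        L[:, rank:] = 0.0
        perm = np.argsort(piv - 1)
        of.gamma = L[perm, :]
        of.eigenvalues = None
        of.n_clipped = A.shape[0] - int(rank)
    else:
        raise ValueError(f"unknown factorization method {method!r}")
    of.method = method
    return of


def _response_rng(seed: int, scenario_id: str) -> np.random.Generator:
    tag = zlib.crc32(scenario_id.encode())
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(tag,)))


def simulate_response(
    factor: OmegaFactor,
    ratios: tuple[float, ...] = DEFAULT_RATIOS,
    n_runs: int = 10000,
    seed: int = 0,
    scenario_id: str = "",
    batch: int = 512,
) -> ResponseCurve:
    """Monte-Carlo response to selection over a grid of selection ratios.

    Per run, draw w = Gamma z (z ~ N(0, I_2n)), split w into true values g
    and predictions g_hat, select the ceil(p n) lines with the largest
    g_hat (ties broken by line order) and record the mean true g of the
    selected set; the achieved response at each ratio is the average over
    runs. Deterministic under (seed, scenario_id).
    """
    if factor.gamma is None:
        factor = factor_omega(factor)
    ratios = np.asarray(ratios, float)
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if ((ratios <= 0) | (ratios > 1)).any():
        raise ValueError("selection ratios must lie in (0, 1]")
    if not (np.diff(ratios) > 0).all():
        raise ValueError("ratios must be strictly increasing")
    n = factor.n
    gamma = factor.gamma
    rng = _response_rng(seed, scenario_id)
    ks = np.ceil(ratios * n).astype(int)
    totals = np.zeros(ratios.size)
    done = 0
    while done < n_runs:
        b = min(batch, n_runs - done)
        z = rng.standard_normal((2 * n, b))
        w = gamma @ z
        g, ghat = w[:n], w[n:]
        # stable ordering: ties in ghat resolved by line index
        order = np.argsort(-ghat, axis=0, kind="stable")
        g_sorted = np.take_along_axis(g, order, axis=0)
        cums = np.cumsum(g_sorted, axis=0)
        for r, k in enumerate(ks):
            totals[r] += cums[k - 1].sum() / k
        done += b
    return ResponseCurve(
        scenario_id=scenario_id,
        ratios=ratios,
        responses=totals / n_runs,
        n_runs=int(n_runs),
        seed=int(seed),
    )


def sample_covariance_check(
    factor: OmegaFactor, n_draws: int = 100000, seed: int = 0
) -> dict:
    """Empirical covariance of simulated w against Omega.

    Returns max absolute element error, the same relative to the largest
    element of Omega, and the draw count; the error shrinks as
    1/sqrt(n_draws) since var(Gamma z) = Gamma Gamma' = Omega exactly.
    """
    if factor.gamma is None:
        factor = factor_omega(factor)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(0xC0,)))
    dim = factor.gamma.shape[0]
    cov = np.zeros((dim, dim))
    done = 0
    chunk = max(1, min(n_draws, int(2e7 // max(dim, 1))))
    while done < n_draws:
        b = min(chunk, n_draws - done)
        w = factor.gamma @ rng.standard_normal((dim, b))
        cov += w @ w.T
        done += b
    cov /= n_draws
    err = np.abs(cov - factor.omega)
    largest = max(float(np.abs(factor.omega).max()), 1e-300)
    return {
        "n_draws": int(n_draws),
        "max_abs_error": float(err.max()),
        "max_rel_error": float(err.max() / largest),
        "empirical_covariance": cov,
    }
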