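"""Multi-environment genomic prediction with genotype-by-environment
interaction.

The model for the observed BLUE cells of a line x environment table is

    y = 1 mu + Zv v + Zg g + gv + e

with v ~ N(0, E sigma_v^2) the environment main effects (E = I by default),
g ~ N(0, G sigma_g^2) the additive genetic main effects under the genomic
relationship matrix G, gv ~ N(0, (Zg G Zg') .* (Zv E Zv') sigma_gv^2) the
interaction effects (one per observed cell; ".*" is the Hadamard product)
and e ~ N(0, I sigma_e^2). Masked cells contribute nothing: they are removed
from y and from every incidence matrix, and predictions for them borrow
information through G.

Variance components are estimated by AI-REML (default, deterministic) or by
a blocked Gibbs sampler with scaled-inverse-chi-square priors; effects and
their prediction error (co)variances come from Henderson's mixed model
equations, whose inverted g-block feeds the response-to-selection machinery
(:mod:`sparsemet.response`).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg

from .genomics import RelationshipMatrix
from .reml import reml
from .stage_one import BlueTable

__all__ = [
    "MetModelSpec",
    "MetFit",
    "MmeSystem",
    "EnvRelationshipMatrix",
    "assemble_mme",
    "estimate_varcomps",
    "fit_met",
    "fit_met_envcor",
    "env_relationship_matrix",
    "predict_cells",
]

_VC_NAMES = ["sigma_v2", "sigma_g2", "sigma_gv2", "sigma_e2"]


@dataclass
class MetModelSpec:
    """Estimation settings for the multi-environment model."""

    method: str = "reml"  # "reml" | "gibbs"
    reml_tol: float = 1e-8
    reml_max_iter: int = 200
    gibbs_iterations: int = 30000
    gibbs_burn_in: int = 5000
    gibbs_thin: int = 10
    gibbs_seed: int = 0
    ridge: float = 1e-6

    def __post_init__(self) -> None:
        if self.method not in ("reml", "gibbs"):
            raise ValueError("method must be 'reml' or 'gibbs'")
        if not self.gibbs_iterations > self.gibbs_burn_in >= 0:
            raise ValueError("need iterations > burn_in >= 0")
        if self.gibbs_thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class EnvRelationshipMatrix:
    """Environment relationship from phenotypic correlations of lines
    commonly observed in pairs of environments."""

    env_names: list[str]
    values: np.ndarray
    common_counts: np.ndarray

    def psd_projected(self) -> np.ndarray:
        """Eigenvalue-clipped PSD repair, diagonal rescaled to one."""
        E = 0.5 * (self.values + self.values.T)
        w, U = np.linalg.eigh(E)
        E = (U * np.clip(w, 0.0, None)) @ U.T
        d = np.sqrt(np.clip(np.diag(E), 1e-12, None))
        E = E / np.outer(d, d)
        np.fill_diagonal(E, 1.0)
        return E


@dataclass
class MmeSystem:
    """Henderson mixed-model equations for (mu, v, g, gv) on observed cells."""

    C: np.ndarray
    rhs: np.ndarray
    slices: dict[str, slice]
    sigma_e2: float

    def solve(self) -> dict[str, np.ndarray]:
        try:
            cf = linalg.cho_factor(self.C, lower=True, check_finite=False)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "MME coefficient matrix not positive definite after ridge; "
                "check the G / E / interaction blocks for singularity"
            ) from exc
        sol = linalg.cho_solve(cf, self.rhs, check_finite=False)
        out = {name: sol[s] for name, s in self.slices.items()}
        out["_cho_factor"] = cf
        return out

    def inverse_block(self, name: str, cf=None) -> np.ndarray:
        """Block of the inverted coefficient matrix, e.g. C^gg."""
        s = self.slices[name]
        if cf is None:
            cf = linalg.cho_factor(self.C, lower=True, check_finite=False)
        rhsI = np.zeros((self.C.shape[0], s.stop - s.start))
        rhsI[s, :] = np.eye(s.stop - s.start)
        cols = linalg.cho_solve(cf, rhsI, check_finite=False)
        return cols[s, :]


@dataclass
class MetFit:
    """Fitted multi-environment genomic model."""

    line_ids: list[str]
    env_names: list[str]
    mu: float
    varcomps: dict[str, float]
    v_hat: np.ndarray
    g_hat: np.ndarray
    gv_hat: np.ndarray
    Cgg: np.ndarray  # g-block of the inverted MME coefficient matrix
    G: np.ndarray
    E: np.ndarray | None
    cell_lines: np.ndarray
    cell_envs: np.ndarray
    y: np.ndarray
    converged: bool = True
    method: str = "reml"
    loglik_trace: list[float] = field(default_factory=list)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def pev_g(self) -> np.ndarray:
        """Prediction error variance matrix of g_hat: C^gg * sigma_e^2."""
        return self.Cgg * self.varcomps["sigma_e2"]

    def g_series(self) -> pd.Series:
        return pd.Series(self.g_hat, index=self.line_ids, name="g_hat")

    def summary(self) -> dict:
        return {
            "mu": self.mu,
            "varcomps": dict(self.varcomps),
            "converged": self.converged,
            "method": self.method,
            "n_observed_cells": int(self.y.size),
        }

    def write_summary(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2))

    def write_gblup_tsv(self, path: str | Path) -> None:
        """Genetic main-effect BLUPs and their PEV diagonal, keyed by line."""
        pd.DataFrame(
            {
                "line": self.line_ids,
                "g_hat": self.g_hat,
                "pev": np.diag(self.pev_g()),
            }
        ).to_csv(path, sep="\t", index=False)


def _cells_and_kernels(blues: BlueTable, G: np.ndarray, E: np.ndarray | None):
    li, ei, y = blues.observed_cells()
    if y.size < 1:
        raise ValueError("no observed cells to fit")
    if not blues.observed.any(axis=1).all():
        raise ValueError("every line must be observed in at least one environment")
    K_g = G[np.ix_(li, li)]
    if E is None:
        K_v = (ei[:, None] == ei[None, :]).astype(float)
    else:
        K_v = E[np.ix_(ei, ei)]
    K_gv = K_g * K_v
    return li, ei, y, K_v, K_g, K_gv


def _as_matrix(G: RelationshipMatrix | np.ndarray, blues: BlueTable) -> np.ndarray:
    if isinstance(G, RelationshipMatrix):
        if list(G.line_ids) != list(blues.line_ids):
            idx = [G.line_ids.index(l) for l in blues.line_ids]
            return G.values[np.ix_(idx, idx)]
        return G.values
    G = np.asarray(G, float)
    if G.shape != (blues.n_lines, blues.n_lines):
        raise ValueError("G dimension does not match the line set")
    return G


def assemble_mme(
    blues: BlueTable,
    G: RelationshipMatrix | np.ndarray,
    varcomps: dict[str, float],
    E: np.ndarray | None = None,
    ridge: float = 1e-6,
) -> MmeSystem:
    """Build Henderson's MME for (mu, v, g, gv) over the observed cells.

    The coefficient matrix is W'W + diag(0, E^-1 k_v, G^-1 k_g, K_gv^-1 k_gv)
    with k_x = sigma_e^2 / sigma_x^2, W = [1 | Zv | Zg | I_N]; covariance
    structures receive a small diagonal ridge before inversion. Its inverse,
    scaled by sigma_e^2, yields prediction error (co)variances.
    """
    Gm = _as_matrix(G, blues)
    li, ei, y, K_v, K_g, K_gv = _cells_and_kernels(blues, Gm, E)
    n, m, N = blues.n_lines, blues.n_envs, y.size
    Zv = np.zeros((N, m))
    Zv[np.arange(N), ei] = 1.0
    Zg = np.zeros((N, n))
    Zg[np.arange(N), li] = 1.0
    W = np.hstack([np.ones((N, 1)), Zv, Zg, np.eye(N)])
    C = W.T @ W
    rhs = W.T @ y
    se2 = float(varcomps["sigma_e2"])
    slices = {
        "mu": slice(0, 1),
        "v": slice(1, 1 + m),
        "g": slice(1 + m, 1 + m + n),
        "gv": slice(1 + m + n, 1 + m + n + N),
    }

    def _inv(A, label):
        try:
            return np.linalg.inv(A + ridge * np.eye(A.shape[0]))
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"{label} covariance block singular even after ridge"
            ) from exc

    Einv = np.eye(m) if E is None else _inv(E, "environment (E)")
    Ginv = _inv(Gm, "genomic (G)")
    # interaction covariance restricted to observed cells; block diagonal by
    # environment when E is the identity
    Kgvinv = _inv(K_gv, "interaction (G x E)")
    C[slices["v"], slices["v"]] += Einv * (se2 / float(varcomps["sigma_v2"]))
    C[slices["g"], slices["g"]] += Ginv * (se2 / float(varcomps["sigma_g2"]))
    C[slices["gv"], slices["gv"]] += Kgvinv * (se2 / float(varcomps["sigma_gv2"]))
    return MmeSystem(C=C, rhs=rhs, slices=slices, sigma_e2=se2)


def estimate_varcomps(
    blues: BlueTable,
    G: RelationshipMatrix | np.ndarray,
    spec: MetModelSpec | None = None,
    E: np.ndarray | None = None,
):
    """Estimate (sigma_v^2, sigma_g^2, sigma_gv^2, sigma_e^2).

    REML (default) maximises the restricted likelihood of the marginal model
    by average information; Gibbs returns posterior means over kept samples.
    Both are reproducible under a fixed seed.

    Returns
    -------
    (varcomps, converged, trace) : dict, bool, list of floats
    """
    spec = spec or MetModelSpec()
    Gm = _as_matrix(G, blues)
    li, ei, y, K_v, K_g, K_gv = _cells_and_kernels(blues, Gm, E)
    if len(np.unique(ei)) < 2:
        raise ValueError("need at least 2 observed environments")
    X = np.ones((y.size, 1))
    if spec.method == "reml":
        res = reml(
            y, X, [K_v, K_g, K_gv],
            names=_VC_NAMES,
            tol=spec.reml_tol,
            max_iter=spec.reml_max_iter,
        )
        if not res.converged:
            warnings.warn(
                f"REML did not reach tolerance in {res.n_iter} iterations; "
                "returning last iterate"
            )
        return res.as_dict(), res.converged, res.loglik_trace
    return _gibbs_varcomps(blues, Gm, spec, E)


def _gibbs_varcomps(blues: BlueTable, Gm: np.ndarray, spec: MetModelSpec, E):
    """Blocked Gibbs sampler: joint location draw from the MME conditional,
    then scaled-inverse-chi-square draws for each variance component.

    Priors are weakly informative scaled-inv-chi2 (df0 = 5) with scales set
    from an equal split of the phenotypic variance, in the spirit of common
    Bayesian GBLUP software defaults.
    """
    li, ei, y, K_v, K_g, K_gv = _cells_and_kernels(blues, Gm, E)
    n, m, N = blues.n_lines, blues.n_envs, y.size
    rng = np.random.default_rng(spec.gibbs_seed)
    Zv = np.zeros((N, m))
    Zv[np.arange(N), ei] = 1.0
    Zg = np.zeros((N, n))
    Zg[np.arange(N), li] = 1.0
    W = np.hstack([np.ones((N, 1)), Zv, Zg, np.eye(N)])
    WtW = W.T @ W
    Wty = W.T @ y
    ridge = spec.ridge
    Einv = np.eye(m) if E is None else np.linalg.inv(E + ridge * np.eye(m))
    Ginv = np.linalg.inv(Gm + ridge * np.eye(n))
    Kgv = Gm[np.ix_(li, li)] * (
        (ei[:, None] == ei[None, :]).astype(float) if E is None else E[np.ix_(ei, ei)]
    )
    Kgvinv = np.linalg.inv(Kgv + ridge * np.eye(N))
    sl = {
        "v": slice(1, 1 + m),
        "g": slice(1 + m, 1 + m + n),
        "gv": slice(1 + m + n, 1 + m + n + N),
    }
    df0 = 5.0
    vy = float(np.var(y))
    S0 = {k: vy / 4.0 * (df0 - 2.0) / df0 for k in _VC_NAMES}
    theta = {k: vy / 4.0 for k in _VC_NAMES}
    qs = {"sigma_v2": m, "sigma_g2": n, "sigma_gv2": N}
    struct = {"sigma_v2": ("v", Einv), "sigma_g2": ("g", Ginv), "sigma_gv2": ("gv", Kgvinv)}
    keep: list[np.ndarray] = []
    for it in range(spec.gibbs_iterations):
        se2 = theta["sigma_e2"]
        C = WtW.copy()
        C[sl["v"], sl["v"]] += Einv * (se2 / theta["sigma_v2"])
        C[sl["g"], sl["g"]] += Ginv * (se2 / theta["sigma_g2"])
        C[sl["gv"], sl["gv"]] += Kgvinv * (se2 / theta["sigma_gv2"])
        Lc = np.linalg.cholesky(C)
        mean = linalg.cho_solve((Lc, True), Wty, check_finite=False)
        z = rng.standard_normal(C.shape[0])
        # theta_loc ~ N(mean, C^-1 sigma_e^2): solve L' x = z
        draw = mean + np.sqrt(se2) * linalg.solve_triangular(
            Lc.T, z, lower=False, check_finite=False
        )
        for name, (key, Sinv) in struct.items():
            u = draw[sl[key]]
            ss = float(u @ (Sinv @ u))
            theta[name] = (ss + df0 * S0[name]) / rng.chisquare(qs[name] + df0)
        eres = y - W @ draw
        theta["sigma_e2"] = (float(eres @ eres) + df0 * S0["sigma_e2"]) / rng.chisquare(
            N + df0
        )
        if it >= spec.gibbs_burn_in and (it - spec.gibbs_burn_in) % spec.gibbs_thin == 0:
            keep.append(np.array([theta[k] for k in _VC_NAMES]))
    post = np.mean(keep, axis=0)
    return dict(zip(_VC_NAMES, post)), True, []


def fit_met(
    blues: BlueTable,
    G: RelationshipMatrix | np.ndarray,
    spec: MetModelSpec | None = None,
    E: np.ndarray | None = None,
    varcomps: dict[str, float] | None = None,
) -> MetFit:
    """Estimate variance components, solve the MME, and return the fit.

    ``varcomps`` may be supplied to skip estimation (e.g. to reuse base-fit
    components across masking replicates).
    """
    spec = spec or MetModelSpec()
    Gm = _as_matrix(G, blues)
    converged, trace = True, []
    if varcomps is None:
        varcomps, converged, trace = estimate_varcomps(blues, Gm, spec, E)
    mme = assemble_mme(blues, Gm, varcomps, E=E, ridge=spec.ridge)
    sol = mme.solve()
    Cgg = mme.inverse_block("g", cf=sol["_cho_factor"])
    li, ei, y = blues.observed_cells()
    return MetFit(
        line_ids=list(blues.line_ids),
        env_names=list(blues.env_names),
        mu=float(sol["mu"][0]),
        varcomps={k: float(v) for k, v in varcomps.items()},
        v_hat=sol["v"],
        g_hat=sol["g"],
        gv_hat=sol["gv"],
        Cgg=0.5 * (Cgg + Cgg.T),
        G=Gm,
        E=None if E is None else np.asarray(E, float),
        cell_lines=li,
        cell_envs=ei,
        y=y,
        converged=bool(converged),
        method=spec.method,
        loglik_trace=list(trace),
    )


def env_relationship_matrix(
    blues: BlueTable, min_overlap: int = 3, fallback: float = 0.0
) -> EnvRelationshipMatrix:
    """Environment relationship E from Pearson correlations of the lines
    commonly observed (unmasked) in each pair of environments.

    Pairs with fewer than ``min_overlap`` common lines fall back to
    ``fallback`` (default 0 = independence) with a warning; the per-pair
    common-line counts are recorded.
    """
    m = blues.n_envs
    vals = blues.masked_values()
    E = np.eye(m)
    counts = np.zeros((m, m), int)
    np.fill_diagonal(counts, blues.observed.sum(axis=0))
    short = []
    for i in range(m):
        for j in range(i + 1, m):
            both = blues.observed[:, i] & blues.observed[:, j]
            counts[i, j] = counts[j, i] = int(both.sum())
            if both.sum() >= min_overlap:
                with np.errstate(invalid="ignore"):
                    r = np.corrcoef(vals[both, i], vals[both, j])[0, 1]
                if np.isnan(r):
                    r = fallback
            else:
                short.append((blues.env_names[i], blues.env_names[j]))
                r = fallback
            E[i, j] = E[j, i] = r
    if short:
        warnings.warn(
            f"insufficient overlap (<{min_overlap} lines) for pairs {short}; "
            f"using fallback {fallback}"
        )
    return EnvRelationshipMatrix(list(blues.env_names), E, counts)


def fit_met_envcor(
    blues: BlueTable,
    G: RelationshipMatrix | np.ndarray,
    E: EnvRelationshipMatrix | np.ndarray,
    spec: MetModelSpec | None = None,
) -> MetFit:
    """Model variant with an environment relationship matrix:
    v ~ N(0, E sigma_v^2) and interaction kernel (Zg G Zg') .* (Zv E Zv')."""
    Em = E.psd_projected() if isinstance(E, EnvRelationshipMatrix) else np.asarray(E, float)
    w = np.linalg.eigvalsh(0.5 * (Em + Em.T))
    if w.min() < -1e-8:
        raise ValueError("environment relationship matrix not PSD after projection")
    if np.allclose(Em, 1.0, atol=1e-10):
        warnings.warn(
            "all-ones environment relationship: interaction kernel collapses "
            "onto the genetic main-effect kernel; sigma_g2 and sigma_gv2 are "
            "confounded"
        )
    return fit_met(blues, G, spec=spec, E=Em)


def predict_cells(fit: MetFit, blues: BlueTable) -> np.ndarray:
    """Predict every cell of the table (observed or masked) from the fit.

    Predicted value = mu + v_e + g_i + BLUP of the interaction for that
    cell; interaction BLUPs for unobserved cells are obtained from their
    covariance with the observed cells (sigma_gv^2 * K_cell,obs) through the
    marginal model.
    """
    li, ei = fit.cell_lines, fit.cell_envs
    n, m = fit.n_lines, len(fit.env_names)
    vc = fit.varcomps
    Em = np.eye(m) if fit.E is None else fit.E
    K_v = Em[np.ix_(ei, ei)]
    K_g = fit.G[np.ix_(li, li)]
    V = vc["sigma_v2"] * K_v + vc["sigma_g2"] * K_g + vc["sigma_gv2"] * (K_g * K_v)
    V += vc["sigma_e2"] * np.eye(li.size)
    resid = np.linalg.solve(V, fit.y - fit.mu)
    pred = np.empty((n, m))
    for j in range(m):
        # covariance of gv at cell (i, j) with the observed cells
        K_cross = fit.G[:, li] * Em[j, ei]
        gv_pred = vc["sigma_gv2"] * (K_cross @ resid)
        pred[:, j] = fit.mu + fit.v_hat[j] + fit.g_hat + gv_pred
    return pred
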