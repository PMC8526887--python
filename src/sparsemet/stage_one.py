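"""Stage-one trial analysis: per-environment BLUEs, repeatability, and
across-environment heritability.

A multi-environment trial is analysed in two stages. Stage one fits each
environment separately: genotype effects are treated as fixed to obtain best
linear unbiased estimates (BLUEs) of line means adjusted for field design
effects (replicate, row, range — all independent random effects), and as
random to obtain the repeatability of the environment. Stage two (the
genomic model, see :mod:`sparsemet.met`) operates on the resulting line x
environment BLUE table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .reml import reml, gls_fixed_effects

__all__ = [
    "PlotTable",
    "BlueTable",
    "StageOneFit",
    "fit_environment",
    "fit_all_environments",
    "cullis_heritability",
    "env_correlations",
]

_DESIGN_COLS = ("rep", "row", "range")


@dataclass
class PlotTable:
    """Plot-level phenotypes: one record per line x environment x replicate.

    The underlying frame has columns ``line``, ``env``, ``rep``, optional
    ``row``/``range``, and ``value``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"line", "env", "rep", "value"}
        missing = need - set(self.frame.columns)
        if missing:
            raise ValueError(f"PlotTable frame missing columns: {sorted(missing)}")
        if self.frame.duplicated(["line", "env", "rep"]).any():
            raise ValueError("duplicate (line, env, rep) records")

    @property
    def env_names(self) -> list[str]:
        return list(pd.unique(self.frame["env"]))

    def write_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "PlotTable":
        return cls(pd.read_csv(path))


@dataclass
class BlueTable:
    """Line x environment BLUEs with an observed/masked indicator.

    ``observed`` marks which cells carry a phenotype; masked cells are
    ignored by every downstream fit (sparse-phenotyping scenarios are just
    BlueTables with part of ``observed`` set False).
    """

    line_ids: list[str]
    env_names: list[str]
    values: np.ndarray
    observed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = len(self.line_ids), len(self.env_names)
        if self.values.shape != (n, m):
            raise ValueError("values shape does not match ids")
        if self.observed is None:
            self.observed = ~np.isnan(self.values)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.observed.shape != (n, m):
            raise ValueError("observed shape does not match ids")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_envs(self) -> int:
        return len(self.env_names)

    def masked_values(self) -> np.ndarray:
        """Values with unobserved cells as NaN."""
        return np.where(self.observed, self.values, np.nan)

    def observed_cells(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(line_index, env_index, y) arrays over observed cells,
        environment-major order."""
        li, ei = np.nonzero(self.observed)
        order = np.lexsort((li, ei))
        li, ei = li[order], ei[order]
        return li, ei, self.values[li, ei]

    def subset_envs(self, envs: list[str]) -> "BlueTable":
        idx = [self.env_names.index(e) for e in envs]
        return BlueTable(
            list(self.line_ids), list(envs), self.values[:, idx].copy(),
            self.observed[:, idx].copy(),
        )

    def with_mask(self, retained: np.ndarray) -> "BlueTable":
        """Copy with ``observed`` replaced by ``retained & observed``."""
        retained = np.asarray(retained, bool)
        if retained.shape != self.observed.shape:
            raise ValueError("mask shape mismatch")
        return BlueTable(
            list(self.line_ids), list(self.env_names), self.values.copy(),
            self.observed & retained,
        )

    def validate_connected(self) -> None:
        if not self.observed.any(axis=1).all():
            bad = [l for l, ok in zip(self.line_ids, self.observed.any(axis=1)) if not ok]
            raise ValueError(f"lines with no observed environment: {bad[:5]}")

    def to_long_frame(self) -> pd.DataFrame:
        li, ei = np.indices(self.values.shape)
        return pd.DataFrame(
            {
                "line": np.asarray(self.line_ids)[li.ravel()],
                "env": np.asarray(self.env_names)[ei.ravel()],
                "value": self.values.ravel(),
                "observed": self.observed.ravel(),
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_long_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "BlueTable":
        df = pd.read_csv(path)
        lines = list(pd.unique(df["line"]).astype(str))
        envs = list(pd.unique(df["env"]).astype(str))
        values = np.full((len(lines), len(envs)), np.nan)
        observed = np.zeros((len(lines), len(envs)), bool)
        lmap = {l: i for i, l in enumerate(lines)}
        emap = {e: j for j, e in enumerate(envs)}
        for rec in df.itertuples(index=False):
            i, j = lmap[str(rec.line)], emap[str(rec.env)]
            values[i, j] = rec.value
            observed[i, j] = bool(getattr(rec, "observed", not np.isnan(rec.value)))
        return cls(lines, envs, values, observed)


@dataclass
class StageOneFit:
    """Per-environment stage-one result."""

    environment: str
    line_ids: list[str]
    blues: np.ndarray
    repeatability: float | None
    genetic_variance: float
    design_variances: dict[str, float]
    residual_variance: float
    converged: bool = True

    def blues_series(self) -> pd.Series:
        return pd.Series(self.blues, index=self.line_ids, name=self.environment)


def _one_hot(codes: np.ndarray, n_levels: int) -> np.ndarray:
    Z = np.zeros((codes.size, n_levels))
    Z[np.arange(codes.size), codes] = 1.0
    return Z


def fit_environment(plots: PlotTable, env: str) -> StageOneFit:
    """Fit one environment: BLUEs (genotype fixed) and repeatability
    (genotype random), design effects random throughout.

    Repeatability is on the line-mean basis,
    ``sigma_g^2 / (sigma_g^2 + sigma_e^2 / r)`` with r the mean number of
    replicates per line; it is unavailable (None) for unreplicated designs.
    """
    sub = plots.frame[plots.frame["env"] == env]
    if sub.empty:
        raise ValueError(f"no records for environment {env!r}")
    y = sub["value"].to_numpy(float)
    lines, line_codes = np.unique(sub["line"].to_numpy(), return_inverse=True)
    design_kernels: list[np.ndarray] = []
    design_names: list[str] = []
    for col in _DESIGN_COLS:
        if col in sub.columns:
            levels, codes = np.unique(sub[col].to_numpy(), return_inverse=True)
            if len(levels) > 1:
                Z = _one_hot(codes, len(levels))
                design_kernels.append(Z @ Z.T)
                design_names.append(col)
    Zl = _one_hot(line_codes, len(lines))

    # genotype fixed -> BLUEs
    if design_kernels:
        fit_f = reml(y, Zl, design_kernels, names=design_names + ["residual"])
        blues, _ = gls_fixed_effects(y, Zl, design_kernels, fit_f.varcomps)
    else:
        blues = np.array([y[line_codes == i].mean() for i in range(len(lines))])
        fit_f = None

    # genotype random -> repeatability
    n_reps = sub.groupby("line")["value"].size()
    if (n_reps < 2).all():
        return StageOneFit(
            environment=str(env), line_ids=[str(l) for l in lines], blues=blues,
            repeatability=None, genetic_variance=np.nan,
            design_variances={}, residual_variance=np.nan,
        )
    X = np.ones((y.size, 1))
    fit_r = reml(
        y, X, [Zl @ Zl.T] + design_kernels,
        names=["genetic"] + design_names + ["residual"],
    )
    vc = fit_r.as_dict()
    r_bar = float(n_reps.mean())
    sg2, se2 = vc["genetic"], vc["residual"]
    repeat = sg2 / (sg2 + se2 / r_bar) if sg2 + se2 > 0 else 0.0
    return StageOneFit(
        environment=str(env),
        line_ids=[str(l) for l in lines],
        blues=blues,
        repeatability=float(repeat),
        genetic_variance=float(sg2),
        design_variances={k: vc[k] for k in design_names},
        residual_variance=float(se2),
        converged=fit_r.converged and (fit_f is None or fit_f.converged),
    )


def fit_all_environments(plots: PlotTable) -> tuple[BlueTable, list[StageOneFit]]:
    """Run stage one for every environment and assemble the BLUE table."""
    fits = [fit_environment(plots, env) for env in plots.env_names]
    lines = list(pd.unique(plots.frame["line"].astype(str)))
    envs = [f.environment for f in fits]
    values = np.full((len(lines), len(envs)), np.nan)
    lmap = {l: i for i, l in enumerate(lines)}
    for j, f in enumerate(fits):
        for l, b in zip(f.line_ids, f.blues):
            values[lmap[l], j] = b
    return BlueTable(lines, envs, values), fits


def stage_one_summary(fits: list[StageOneFit]) -> pd.DataFrame:
    """One row per environment: repeatability and variance components."""
    return pd.DataFrame(
        {
            "environment": [f.environment for f in fits],
            "repeatability": [f.repeatability for f in fits],
            "genetic_variance": [f.genetic_variance for f in fits],
            "residual_variance": [f.residual_variance for f in fits],
            "converged": [f.converged for f in fits],
        }
    )


def cullis_heritability(blues: BlueTable) -> float:
    """Across-environment heritability h2 = 1 - cbar / (2 sigma_l^2).

    Fits BLUE = mu + environment + line + error with environment and line as
    independent random effects (REML), then computes cbar, the mean variance
    of a difference between two line BLUPs, from the line block of the
    inverted mixed-model equations. Clipped to [0, 1].
    """
    li, ei, y = blues.observed_cells()
    if blues.n_envs < 2:
        raise ValueError("need at least 2 environments for heritability")
    t = blues.n_lines
    if t < 3:
        raise ValueError("need at least 3 lines for heritability")
    Zr = _one_hot(ei, blues.n_envs)
    Zl = _one_hot(li, t)
    X = np.ones((y.size, 1))
    fit = reml(y, X, [Zr @ Zr.T, Zl @ Zl.T], names=["env", "line", "residual"])
    sr2, sl2, se2 = fit.varcomps
    if sl2 <= 1e-9 * max(1.0, float(np.var(y))):
        warnings.warn("line variance is (numerically) zero; h2 = 0")
        return 0.0
    # Henderson MME for (mu, r, l); PEV of line BLUPs from the l-block of C^-1
    W = np.hstack([X, Zr, Zl])
    C = W.T @ W
    m = blues.n_envs
    idx_r = slice(1, 1 + m)
    idx_l = slice(1 + m, 1 + m + t)
    C[idx_r, idx_r] += np.eye(m) * (se2 / sr2)
    C[idx_l, idx_l] += np.eye(t) * (se2 / sl2)
    Cinv = np.linalg.inv(C)
    pev = Cinv[idx_l, idx_l] * se2
    tr = float(np.trace(pev))
    cbar = 2.0 * (t * tr - float(pev.sum())) / (t * (t - 1))
    return float(np.clip(1.0 - cbar / (2.0 * sl2), 0.0, 1.0))


def env_correlations(blues: BlueTable, min_overlap: int = 3) -> pd.DataFrame:
    """Pairwise Pearson correlation of environment BLUE columns.

    Uses pairwise-complete observations (masked cells excluded); pairs with
    fewer than ``min_overlap`` jointly observed lines get NaN with a warning.
    """
    df = pd.DataFrame(blues.masked_values(), columns=blues.env_names)
    corr = df.corr(method="pearson", min_periods=min_overlap)
    np.fill_diagonal(corr.values, 1.0)
    if corr.isna().any().any():
        warnings.warn(
            f"environment pairs with < {min_overlap} shared lines: correlation NaN"
        )
    return corr
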