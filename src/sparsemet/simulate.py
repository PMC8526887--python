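"""Synthetic multi-environment trial (MET) generator.

Emulates the structure of a pureline breeding panel evaluated for grain
yield across several year x time-of-sowing environments: fully inbred lines
(dosages 0/2) organised in families, biallelic SNPs with bounded minor
allele frequency, environment-specific true genetic values with a requested
genetic correlation matrix between environments, and phenotypes at either
plot level (randomised complete block design with replicate/row/range
effects) or directly at BLUE level with noise calibrated to a requested
per-environment repeatability.

All randomness flows through one integer seed; each generation stage draws
from a deterministically derived substream, so identical specs give
bit-identical outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genomics import GenotypeMatrix
from .stage_one import BlueTable, PlotTable

__all__ = [
    "SimSpec",
    "TrueGeneticValues",
    "simulate_genotypes",
    "simulate_true_values",
    "simulate_plot_data",
    "simulate_blues",
    "simulate_dataset",
    "wheat_like_spec",
    "rice_like_spec",
    "WHEAT_LIKE_CORRELATION",
    "RICE_LIKE_CORRELATION",
]

# Six environments, one pair highly positively correlated (0.84), four
# negative pairs, and low/moderate positives elsewhere -- the qualitative
# pattern of a wheat panel grown over three years at two sowing times, where
# sowing-time contrasts within a year can invert genotype rankings.
WHEAT_LIKE_CORRELATION = np.array(
    [
        [1.00, 0.84, 0.08, 0.06, 0.10, 0.05],
        [0.84, 1.00, -0.28, -0.25, -0.26, -0.22],
        [0.08, -0.28, 1.00, -0.15, 0.38, 0.32],
        [0.06, -0.25, -0.15, 1.00, 0.25, 0.30],
        [0.10, -0.26, 0.38, 0.25, 1.00, 0.40],
        [0.05, -0.22, 0.32, 0.30, 0.40, 1.00],
    ]
)

# All-positive correlations from 0.05 to 0.67: one highly correlated pair and
# one triple of mutually lowly correlated (< 0.18) environments.
RICE_LIKE_CORRELATION = np.array(
    [
        [1.00, 0.67, 0.30, 0.12, 0.25, 0.20],
        [0.67, 1.00, 0.35, 0.22, 0.15, 0.28],
        [0.30, 0.35, 1.00, 0.40, 0.32, 0.10],
        [0.12, 0.22, 0.40, 1.00, 0.08, 0.14],
        [0.25, 0.15, 0.32, 0.08, 1.00, 0.05],
        [0.20, 0.28, 0.10, 0.14, 0.05, 1.00],
    ]
)


@dataclass
class SimSpec:
    """Full specification of a synthetic MET dataset.

    Parameters
    ----------
    n_lines, n_families, n_markers : panel dimensions. Lines are split into
        near-equal families sharing a simulated common parent.
    maf_range : (low, high) ancestral counted-allele frequency bounds,
        within (0, 0.5].
    env_names : environment identifiers (length m).
    env_genetic_correlation : m x m genetic correlation between
        environment-specific true values; must be symmetric PSD with unit
        diagonal.
    genetic_variance_per_env : m positive genetic variances (yield units^2).
    repeatability_per_env : m line-mean repeatabilities in (0, 1); calibrates
        the phenotypic noise.
    n_replicates : replicates per environment (RCBD blocks).
    seed : master seed; all stages derive substreams from it.
    family_drift : Beta concentration of family allele frequencies around the
        ancestral frequency; smaller values give stronger family structure.
    heterozygosity_rate : probability a call is drawn as two independent
        gametes instead of a doubled one (residual heterozygosity).
    missing_rate : probability a dosage call is missing.
    env_mean, env_mean_sd : normal distribution of environment means.
    design_variance_fraction : variance of each of the replicate/row/range
        effects as a fraction of the environment's genetic variance.
    """

    n_lines: int
    n_families: int
    n_markers: int
    env_names: list[str]
    env_genetic_correlation: np.ndarray
    genetic_variance_per_env: np.ndarray
    repeatability_per_env: np.ndarray
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_replicates: int = 2
    seed: int = 0
    family_drift: float = 8.0
    heterozygosity_rate: float = 0.0
    missing_rate: float = 0.0
    env_mean: float = 4.0
    env_mean_sd: float = 0.8
    design_variance_fraction: float = 0.15

    def __post_init__(self) -> None:
        self.env_genetic_correlation = np.asarray(self.env_genetic_correlation, float)
        self.genetic_variance_per_env = np.asarray(self.genetic_variance_per_env, float)
        self.repeatability_per_env = np.asarray(self.repeatability_per_env, float)
        m = len(self.env_names)
        if m == 0 or self.n_lines < 1 or self.n_markers < 1:
            raise ValueError("empty specification")
        if not 1 <= self.n_families <= self.n_lines:
            raise ValueError("need 1 <= n_families <= n_lines")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        R = self.env_genetic_correlation
        if R.shape != (m, m) or not np.allclose(R, R.T, atol=1e-10):
            raise ValueError("env_genetic_correlation must be m x m symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-8):
            raise ValueError("env_genetic_correlation must have unit diagonal")
        if np.linalg.eigvalsh(R).min() < -1e-8:
            raise ValueError("env_genetic_correlation is not positive semidefinite")
        if self.genetic_variance_per_env.shape != (m,) or (
            self.genetic_variance_per_env <= 0
        ).any():
            raise ValueError("genetic_variance_per_env must be m positive reals")
        if self.repeatability_per_env.shape != (m,) or not (
            (self.repeatability_per_env > 0) & (self.repeatability_per_env < 1)
        ).all():
            raise ValueError("repeatability_per_env must lie in (0, 1)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def n_envs(self) -> int:
        return len(self.env_names)

    def rng(self, stage: int) -> np.random.Generator:
        """Deterministic substream for a generation stage."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=int(self.seed), spawn_key=(stage,))
        )

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimSpec":
        d = json.loads(Path(path).read_text())
        d["maf_range"] = tuple(d["maf_range"])
        return cls(**d)


@dataclass
class TrueGeneticValues:
    """Latent environment-specific genetic values u_e (lines x envs).

    The genomic model decomposes these into a main effect shared across
    environments and a genotype-by-environment deviation; the generator only
    commits to their covariance: cov(u_.e, u_.f) = G * Sigma[e, f] with G the
    realised genomic relationship of the panel and Sigma the requested
    genetic covariance between environments.
    """

    line_ids: list[str]
    env_names: list[str]
    values: np.ndarray
    marker_effects: np.ndarray | None = None

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.line_ids, columns=self.env_names)


_STAGE_GENO, _STAGE_TRUTH, _STAGE_ENVMEANS, _STAGE_PLOTS, _STAGE_BLUES = range(5)


def simulate_genotypes(spec: SimSpec) -> GenotypeMatrix:
    """Draw SNP genotypes for a family-structured panel of inbred lines.

    Ancestral counted-allele frequencies are uniform on ``maf_range``; each
    family drifts around them via a Beta(p*theta, (1-p)*theta) draw
    (theta = ``family_drift``), and fully inbred line genotypes are doubled
    Bernoulli gametes from the family frequency, giving dosages in {0, 2}
    (plus heterozygotes/missing at the configured rates).
    """
    rng = spec.rng(_STAGE_GENO)
    lo, hi = spec.maf_range
    p_anc = rng.uniform(lo, hi, size=spec.n_markers)
    fam_sizes = [len(a) for a in np.array_split(np.arange(spec.n_lines), spec.n_families)]
    theta = spec.family_drift
    rows = []
    for size in fam_sizes:
        f = rng.beta(p_anc * theta, (1.0 - p_anc) * theta)
        a1 = (rng.random((size, spec.n_markers)) < f).astype(float)
        if spec.heterozygosity_rate > 0:
            a2 = (rng.random((size, spec.n_markers)) < f).astype(float)
            keep_het = rng.random((size, spec.n_markers)) < spec.heterozygosity_rate
            dos = np.where(keep_het, a1 + a2, 2.0 * a1)
        else:
            dos = 2.0 * a1
        rows.append(dos)
    dosages = np.vstack(rows)
    if spec.missing_rate > 0:
        miss = rng.random(dosages.shape) < spec.missing_rate
        dosages = np.where(miss, np.nan, dosages)
    line_ids = [f"L{i + 1:04d}" for i in range(spec.n_lines)]
    marker_ids = [f"M{j + 1:06d}" for j in range(spec.n_markers)]
    return GenotypeMatrix(line_ids, marker_ids, dosages)


def simulate_true_values(geno: GenotypeMatrix, spec: SimSpec) -> TrueGeneticValues:
    """Environment-specific true genetic values from a marker-effect model.

    Marker effects are drawn per marker as correlated normal vectors across
    environments, with covariance Sigma / c where Sigma is the requested
    genetic covariance (correlation scaled by per-environment variances) and
    c is the mean per-line sum of squared centred dosages; true values are
    centred dosages times effects, so their across-line covariance is
    proportional to the VanRaden relationship of the same panel, scaled so
    that the realised variance of u_e matches the requested
    ``genetic_variance_per_env`` (inbred panels, whose relationship diagonal
    is near 2 rather than 1, would otherwise double it). Empirical
    environment correlations converge to the request as markers and lines
    grow.
    """
    rng = spec.rng(_STAGE_TRUTH)
    m = spec.n_envs
    sd = np.sqrt(spec.genetic_variance_per_env)
    Sigma = spec.env_genetic_correlation * np.outer(sd, sd)
    p = geno.allele_frequencies()
    Zc = np.where(np.isnan(geno.dosages), 2.0 * p, geno.dosages) - 2.0 * p
    c = float((Zc**2).sum(axis=1).mean())
    if c <= 0:
        raise ValueError("panel has no polymorphic markers")
    # PSD square root of Sigma (Cholesky can fail at correlation +-1)
    w, U = np.linalg.eigh(Sigma)
    root = U @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    alpha = rng.standard_normal((geno.n_markers, m)) @ root.T / np.sqrt(c)
    u = Zc @ alpha
    return TrueGeneticValues(
        list(geno.line_ids), list(spec.env_names), u, marker_effects=alpha
    )


def _env_means(spec: SimSpec) -> np.ndarray:
    rng = spec.rng(_STAGE_ENVMEANS)
    return spec.env_mean + spec.env_mean_sd * rng.standard_normal(spec.n_envs)


def simulate_plot_data(truth: TrueGeneticValues, spec: SimSpec) -> PlotTable:
    """Plot-level phenotypes from an RCBD field layout.

    y = env mean + u_e(line) + replicate + row + range + plot error, one
    record per line x environment x replicate. The plot error variance is
    calibrated so the line-mean repeatability equals the request:
    sigma_plot^2 = n_reps * sigma_g^2 * (1 - r) / r. Replicate, row and range
    effects each have variance ``design_variance_fraction * sigma_g^2``;
    they do not enter the repeatability, which is defined net of design
    effects.
    """
    rng = spec.rng(_STAGE_PLOTS)
    means = _env_means(spec)
    n = spec.n_lines
    n_rows = int(np.ceil(np.sqrt(n)))
    n_ranges = int(np.ceil(n / n_rows))
    recs = []
    for j, env in enumerate(spec.env_names):
        sg2 = spec.genetic_variance_per_env[j]
        r = spec.repeatability_per_env[j]
        sigma_plot = np.sqrt(spec.n_replicates * sg2 * (1.0 - r) / r)
        sd_design = np.sqrt(spec.design_variance_fraction * sg2)
        rep_eff = sd_design * rng.standard_normal(spec.n_replicates)
        row_eff = sd_design * rng.standard_normal(n_rows)
        range_eff = sd_design * rng.standard_normal(n_ranges)
        for rep in range(spec.n_replicates):
            pos = rng.permutation(n)
            rows_idx = pos % n_rows
            ranges_idx = pos // n_rows
            err = sigma_plot * rng.standard_normal(n)
            y = (
                means[j]
                + truth.values[:, j]
                + rep_eff[rep]
                + row_eff[rows_idx]
                + range_eff[ranges_idx]
                + err
            )
            for i in range(n):
                recs.append(
                    (
                        truth.line_ids[i],
                        env,
                        f"rep{rep + 1}",
                        f"row{rows_idx[i] + 1}",
                        f"range{ranges_idx[i] + 1}",
                        y[i],
                    )
                )
    frame = pd.DataFrame(recs, columns=["line", "env", "rep", "row", "range", "value"])
    return PlotTable(frame)


def simulate_blues(truth: TrueGeneticValues, spec: SimSpec) -> BlueTable:
    """BLUE-level phenotypes, skipping the field design.

    BLUE = env mean + u_e + noise with noise variance
    sigma_g^2 (1 - r) / r, the error variance of a line mean over
    ``n_replicates`` plots at repeatability r.
    """
    rng = spec.rng(_STAGE_BLUES)
    means = _env_means(spec)
    sg2 = spec.genetic_variance_per_env
    r = spec.repeatability_per_env
    noise_sd = np.sqrt(sg2 * (1.0 - r) / r)
    noise = rng.standard_normal(truth.values.shape) * noise_sd
    values = means + truth.values + noise
    return BlueTable(list(truth.line_ids), list(spec.env_names), values)


def simulate_dataset(spec: SimSpec):
    """Convenience: genotypes, truth and BLUEs in one call."""
    geno = simulate_genotypes(spec)
    truth = simulate_true_values(geno, spec)
    blues = simulate_blues(truth, spec)
    return geno, truth, blues


def wheat_like_spec(
    n_lines: int = 189,
    n_markers: int = 2000,
    n_families: int = 8,
    seed: int = 0,
    **overrides,
) -> SimSpec:
    """A wheat-like panel: 6 environments spanning correlations from
    negative to 0.84, repeatabilities above 0.4, two replicates."""
    defaults = dict(
        n_lines=n_lines,
        n_families=n_families,
        n_markers=n_markers,
        env_names=["Y1_TOS1", "Y1_TOS2", "Y2_TOS1", "Y2_TOS2", "Y3_TOS1", "Y3_TOS2"],
        env_genetic_correlation=WHEAT_LIKE_CORRELATION.copy(),
        genetic_variance_per_env=np.full(6, 0.25),
        repeatability_per_env=np.array([0.75, 0.80, 0.70, 0.75, 0.80, 0.70]),
        n_replicates=2,
        seed=seed,
    )
    defaults.update(overrides)
    return SimSpec(**defaults)


def rice_like_spec(
    n_lines: int = 160,
    n_markers: int = 2000,
    n_families: int = 6,
    seed: int = 0,
    **overrides,
) -> SimSpec:
    """A rice-like panel: 6 environments with all-positive correlations
    from 0.05 to 0.67."""
    defaults = dict(
        n_lines=n_lines,
        n_families=n_families,
        n_markers=n_markers,
        env_names=["Y1_S1", "Y1_S2", "Y2_S1", "Y2_S2", "Y3_S1", "Y3_S2"],
        env_genetic_correlation=RICE_LIKE_CORRELATION.copy(),
        genetic_variance_per_env=np.full(6, 0.20),
        repeatability_per_env=np.array([0.80, 0.85, 0.75, 0.70, 0.75, 0.80]),
        n_replicates=2,
        seed=seed,
    )
    defaults.update(overrides)
    return SimSpec(**defaults)
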