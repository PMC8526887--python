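"""End-to-end comparison of complete and sparse phenotyping scenarios.

For every base combination of ``n_base`` environments the pipeline fits the
multi-environment genomic model on the complete base table and simulates its
response to selection; every extension scenario is then fitted on many random
CV2 masking replicates and its responses compared with the complete
scenario's achieved response by one-sample Student's t tests at each
selection ratio. A scenario is declared better ("sparse_higher") only when
the difference is significant with a positive mean at every ratio.

Base combinations are also classified into groups by the pattern of their
pairwise environment correlations (one highly positive pair / all positive /
one negative pair / two or more negative pairs), the structure that predicts
where sparse phenotyping pays off.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .design import (
    CombinationPlan,
    enumerate_base_combinations,
    enumerate_extensions,
    generate_mask,
)
from .genomics import RelationshipMatrix
from .met import MetModelSpec, fit_met
from .response import (
    DEFAULT_RATIOS,
    ResponseCurve,
    build_omega,
    factor_omega,
    simulate_response,
)
from .stage_one import BlueTable, env_correlations

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "ScenarioComparison",
    "CombinationGroup",
    "ClassificationThresholds",
    "run_experiment",
    "test_scenario",
    "classify_combination",
    "summarize_by_extension_size",
]

logger = logging.getLogger(__name__)


@dataclass
class ClassificationThresholds:
    """Cutoffs for grouping base combinations by correlation pattern.

    style="wheat": negative correlations drive the grouping (boundary 0);
    style="rice": correlations below ``low_positive`` play the role of the
    negative ones (all-positive panels).
    """

    style: str = "wheat"
    high_positive: float = 0.8
    negative_boundary: float = 0.0
    low_positive: float = 0.18

    def __post_init__(self) -> None:
        if self.style not in ("wheat", "rice"):
            raise ValueError("style must be 'wheat' or 'rice'")
        if self.style == "rice" and not self.low_positive < self.high_positive:
            raise ValueError("unreachable grouping: low_positive >= high_positive")


@dataclass
class CombinationGroup:
    base_envs: tuple[str, ...]
    group: int
    rule: str


@dataclass
class ScenarioComparison:
    """Per-ratio t tests of sparse replicates against the complete response."""

    base_id: str
    extension_id: str
    extension_size: int
    ratios: np.ndarray
    complete_response: np.ndarray
    sparse_mean: np.ndarray
    mean_difference: np.ndarray
    t_statistics: np.ndarray
    p_values: np.ndarray
    verdict: str
    n_sparse_replicates: int
    n_failed_replicates: int = 0


@dataclass
class ExperimentConfig:
    """Knobs of the full experiment; reproducible from (config, seed)."""

    n_base: int = 3
    extension_sizes: tuple[int, ...] = (1, 2, 3)
    n_mask_replicates: int = 100
    selection_ratios: tuple[float, ...] = DEFAULT_RATIOS
    n_runs: int = 10000
    alpha: float = 0.05
    seed: int = 0
    met_spec: MetModelSpec = field(default_factory=MetModelSpec)
    thresholds: ClassificationThresholds = field(default_factory=ClassificationThresholds)
    reuse_varcomps: bool = False
    bonferroni: bool = False
    bases: tuple[tuple[str, ...], ...] | None = None
    plans: tuple[CombinationPlan, ...] | None = None


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    groups: dict[tuple[str, ...], CombinationGroup]
    complete_curves: dict[str, ResponseCurve]
    comparisons: list[ScenarioComparison]
    failures: list[tuple[str, str]] = field(default_factory=list)

    def comparison_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.comparisons:
            base = tuple(sorted(c.base_id[5:-1].split(",")))
            grp = self.groups.get(base)
            rows.append(
                {
                    "base_id": c.base_id,
                    "extension_id": c.extension_id,
                    "extension_size": c.extension_size,
                    "group": grp.group if grp else None,
                    "verdict": c.verdict,
                    "min_mean_difference": float(c.mean_difference.min()),
                    "max_p_value": float(c.p_values.max()),
                    "n_sparse_replicates": c.n_sparse_replicates,
                    "n_failed_replicates": c.n_failed_replicates,
                }
            )
        return pd.DataFrame(rows)


def classify_combination(
    cor: pd.DataFrame | np.ndarray,
    base: CombinationPlan | tuple[str, ...],
    thresholds: ClassificationThresholds | None = None,
    env_names: list[str] | None = None,
) -> CombinationGroup:
    """Assign a base combination to a correlation-pattern group.

    Wheat-style groups: (1) any within-base pair at or above the
    high-positive cutoff; (2) all pairs positive; (3) exactly one negative
    pair; (4) two or more negative pairs. Rice-style replaces "negative"
    with "below the low-positive cutoff". Rules are checked in order 1..4.
    """
    thresholds = thresholds or ClassificationThresholds()
    base_envs = base.base_envs if isinstance(base, CombinationPlan) else tuple(base)
    if isinstance(cor, pd.DataFrame):
        sub = cor.loc[list(base_envs), list(base_envs)].to_numpy()
    else:
        if env_names is None:
            raise ValueError("env_names required with an ndarray correlation matrix")
        idx = [env_names.index(e) for e in base_envs]
        sub = np.asarray(cor, float)[np.ix_(idx, idx)]
    iu = np.triu_indices(len(base_envs), k=1)
    pairs = sub[iu]
    lo = (
        thresholds.negative_boundary
        if thresholds.style == "wheat"
        else thresholds.low_positive
    )
    n_low = int((pairs < lo).sum())
    if (pairs >= thresholds.high_positive).any():
        return CombinationGroup(base_envs, 1, "high_positive_pair")
    if n_low == 0:
        return CombinationGroup(base_envs, 2, "all_pairs_above_cutoff")
    if n_low == 1:
        return CombinationGroup(base_envs, 3, "one_pair_below_cutoff")
    return CombinationGroup(base_envs, 4, "two_or_more_pairs_below_cutoff")


def test_scenario(
    complete: ResponseCurve,
    sparse_replicates: list[ResponseCurve],
    alpha: float = 0.05,
    bonferroni_m: int = 1,
    n_failed: int = 0,
    extension_size: int = 0,
    extension_id: str = "",
) -> ScenarioComparison:
    """One-sample two-sided t tests of the sparse responses against the
    complete scenario's achieved response (a constant reference) per ratio.

    Verdict "sparse_higher" requires a significant positive mean difference
    at every selection ratio (and symmetrically for "sparse_lower");
    otherwise "no_difference". With zero variance across replicates the
    comparison degenerates to an exact comparison of means (p = 0 or 1).
    """
    if len(sparse_replicates) < 2:
        raise ValueError("need at least 2 sparse replicates for a t test")
    ratios = complete.ratios
    for rc in sparse_replicates:
        if not np.allclose(rc.ratios, ratios):
            raise ValueError("sparse replicates on a different ratio grid")
    S = np.vstack([rc.responses for rc in sparse_replicates])
    ref = complete.responses
    diffs = S - ref
    md = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    nrep = S.shape[0]
    tstat = np.empty(ratios.size)
    pval = np.empty(ratios.size)
    for r in range(ratios.size):
        if sd[r] == 0.0:
            tstat[r] = np.inf * np.sign(md[r]) if md[r] != 0 else 0.0
            pval[r] = 0.0 if md[r] != 0 else 1.0
        else:
            res = stats.ttest_1samp(S[:, r], popmean=ref[r])
            tstat[r], pval[r] = float(res.statistic), float(res.pvalue)
    alpha_eff = alpha / max(bonferroni_m, 1)
    sig = pval < alpha_eff
    if sig.all() and (md > 0).all():
        verdict = "sparse_higher"
    elif sig.all() and (md < 0).all():
        verdict = "sparse_lower"
    else:
        verdict = "no_difference"
    return ScenarioComparison(
        base_id=complete.scenario_id,
        extension_id=extension_id,
        extension_size=extension_size,
        ratios=np.asarray(ratios, float),
        complete_response=ref.copy(),
        sparse_mean=S.mean(axis=0),
        mean_difference=md,
        t_statistics=tstat,
        p_values=pval,
        verdict=verdict,
        n_sparse_replicates=nrep,
        n_failed_replicates=n_failed,
    )


def _fit_and_respond(blues, G, config, scenario_id, varcomps=None):
    fit = fit_met(blues, G, spec=config.met_spec, varcomps=varcomps)
    factor = factor_omega(build_omega(fit))
    curve = simulate_response(
        factor,
        ratios=config.selection_ratios,
        n_runs=config.n_runs,
        seed=config.seed,
        scenario_id=scenario_id,
    )
    return fit, curve


def run_experiment(
    blues: BlueTable,
    G: RelationshipMatrix | np.ndarray,
    config: ExperimentConfig | None = None,
) -> ExperimentResult:
    """Run the full complete-vs-sparse comparison.

    For every base combination (all C(m, n_base) unless restricted by
    ``config.bases`` or ``config.plans``): fit the complete base scenario and
    simulate its response curve; for every extension plan and masking
    replicate, mask, refit (re-estimating variance components unless
    ``reuse_varcomps``), simulate, and t-test against the complete response.
    Scenarios whose fit fails are recorded and skipped. Fully reproducible
    from (config, seed).
    """
    config = config or ExperimentConfig()
    blues.validate_connected()
    corr = env_correlations(blues)
    env_names = list(blues.env_names)

    if config.plans is not None:
        ext_plans = list(config.plans)
        base_sets = sorted({p.base_envs for p in ext_plans})
        base_plans = [CombinationPlan(b) for b in base_sets]
    else:
        base_plans = enumerate_base_combinations(env_names, config.n_base)
        if config.bases is not None:
            wanted = {tuple(sorted(b)) for b in config.bases}
            base_plans = [p for p in base_plans if tuple(sorted(p.base_envs)) in wanted]
        ext_plans = []
        for bp in base_plans:
            ext_plans.extend(
                enumerate_extensions(bp, env_names, sizes=config.extension_sizes)
            )

    groups = {
        tuple(sorted(bp.base_envs)): classify_combination(corr, bp, config.thresholds)
        for bp in base_plans
    }

    complete_curves: dict[str, ResponseCurve] = {}
    failures: list[tuple[str, str]] = []
    for bp in base_plans:
        sub = blues.subset_envs(list(bp.base_envs))
        try:
            _, curve = _fit_and_respond(sub, G, config, bp.scenario_id)
            complete_curves[bp.scenario_id] = curve
        except Exception as exc:  # recorded, pipeline continues
            logger.warning("complete scenario %s failed: %s", bp.scenario_id, exc)
            failures.append((bp.scenario_id, str(exc)))

    n_tests = len(ext_plans) if config.bonferroni else 1
    comparisons: list[ScenarioComparison] = []
    for plan in ext_plans:
        base_id = CombinationPlan(plan.base_envs).scenario_id
        if base_id not in complete_curves:
            continue
        sub_all = blues.subset_envs(list(plan.all_envs))
        base_varcomps = None
        if config.reuse_varcomps:
            try:
                from .met import estimate_varcomps

                base_varcomps, *_ = estimate_varcomps(sub_all, G, config.met_spec)
            except Exception as exc:
                failures.append((plan.scenario_id, f"varcomps: {exc}"))
                continue
        replicates: list[ResponseCurve] = []
        n_failed = 0
        for rep in range(1, config.n_mask_replicates + 1):
            mask = generate_mask(plan, list(blues.line_ids), rep, config.seed)
            masked = sub_all.with_mask(mask.retained)
            try:
                _, curve = _fit_and_respond(
                    masked, G, config, mask.scenario_id, varcomps=base_varcomps
                )
                replicates.append(curve)
            except Exception as exc:
                n_failed += 1
                failures.append((mask.scenario_id, str(exc)))
        if len(replicates) < 2:
            failures.append((plan.scenario_id, "fewer than 2 successful replicates"))
            continue
        logger.info("scenario %s: %d replicates fitted", plan.scenario_id, len(replicates))
        comparisons.append(
            test_scenario(
                complete_curves[base_id],
                replicates,
                alpha=config.alpha,
                bonferroni_m=n_tests,
                n_failed=n_failed,
                extension_size=len(plan.extension_envs),
                extension_id=plan.scenario_id,
            )
        )
    return ExperimentResult(
        config=config,
        groups=groups,
        complete_curves=complete_curves,
        comparisons=comparisons,
        failures=failures,
    )


def summarize_by_extension_size(
    comparisons: list[ScenarioComparison],
) -> pd.DataFrame:
    """Mean achieved sparse response per base and extension size, with a flag
    for bases where one-environment extensions dominate larger ones."""
    rows = []
    for c in comparisons:
        rows.append(
            {
                "base_id": c.base_id,
                "extension_size": c.extension_size,
                "mean_sparse_response": float(c.sparse_mean.mean()),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    agg = (
        df.groupby(["base_id", "extension_size"])["mean_sparse_response"]
        .mean()
        .unstack("extension_size")
    )
    flags = []
    for _, row in agg.iterrows():
        vals = row.dropna()
        if 1 in vals.index and len(vals) > 1:
            flags.append(bool(vals[1] > vals.drop(index=1).max()))
        else:
            flags.append(False)
    agg["size1_dominates"] = flags
    return agg.reset_index()
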