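"""Sparse-phenotyping designs: environment combinations and CV2 masks.

A "complete phenotyping" scenario phenotypes every line in a base set of
three environments. A sparse scenario extends the base by one to three
extension environments and masks phenotypes cell-wise (cross-validation
scheme CV2) so that every line keeps exactly as many observations as the
base size — retention 3/4 = 75%, 3/5 = 60% and 3/6 = 50% for 4-, 5- and
6-environment scenarios. Total phenotyping intensity is therefore identical
across all scenarios built on the same line set.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CombinationPlan",
    "MaskScenario",
    "enumerate_base_combinations",
    "enumerate_extensions",
    "masks_per_line",
    "generate_mask",
]


@dataclass(frozen=True)
class CombinationPlan:
    """A base environment set plus an ordered tuple of extension environments."""

    base_envs: tuple[str, ...]
    extension_envs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if set(self.base_envs) & set(self.extension_envs):
            raise ValueError("base and extension environments must be disjoint")

    @property
    def all_envs(self) -> tuple[str, ...]:
        return self.base_envs + self.extension_envs

    @property
    def n_envs(self) -> int:
        return len(self.all_envs)

    @property
    def scenario_id(self) -> str:
        base = ",".join(sorted(self.base_envs))
        if not self.extension_envs:
            return f"base{{{base}}}"
        ext = ",".join(sorted(self.extension_envs))
        return f"base{{{base}}}+ext{{{ext}}}"

    @property
    def retention(self) -> float:
        """Fraction of cells retained under intensity-matched masking."""
        return len(self.base_envs) / self.n_envs


@dataclass
class MaskScenario:
    """One random CV2 masking replicate of a combination plan.

    ``retained`` is a lines x scenario-environments boolean matrix; True
    means the phenotype is kept. Every line keeps exactly
    ``len(plan.base_envs)`` observations.
    """

    plan: CombinationPlan
    replicate_index: int
    line_ids: list[str]
    retained: np.ndarray
    seed: int

    @property
    def scenario_id(self) -> str:
        return f"{self.plan.scenario_id}#rep{self.replicate_index}"

    def retained_fraction(self) -> float:
        return float(self.retained.mean())

    def to_frame(self) -> pd.DataFrame:
        li, ei = np.indices(self.retained.shape)
        return pd.DataFrame(
            {
                "line": np.asarray(self.line_ids)[li.ravel()],
                "env": np.asarray(self.plan.all_envs)[ei.ravel()],
                "observed": self.retained.ravel(),
            }
        )

    def write(self, csv_path: str | Path, meta_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        if meta_path is not None:
            meta = {
                "scenario_id": self.scenario_id,
                "base_envs": list(self.plan.base_envs),
                "extension_envs": list(self.plan.extension_envs),
                "replicate_index": self.replicate_index,
                "seed": self.seed,
            }
            Path(meta_path).write_text(json.dumps(meta, indent=2))


def enumerate_base_combinations(env_names: list[str], k: int = 3) -> list[CombinationPlan]:
    """All C(m, k) base combinations, in deterministic lexicographic order
    of environment positions. With six environments and k = 3 there are 20."""
    if k > len(env_names):
        raise ValueError(f"cannot choose {k} environments out of {len(env_names)}")
    return [CombinationPlan(tuple(c)) for c in combinations(env_names, k)]


def enumerate_extensions(
    plan: CombinationPlan, all_envs: list[str], sizes: tuple[int, ...] = (1, 2, 3)
) -> list[CombinationPlan]:
    """Extend a base combination by every subset of the remaining
    environments with the requested sizes.

    With three remaining environments this yields three 1-extensions, three
    2-extensions and one 3-extension.
    """
    remaining = [e for e in all_envs if e not in plan.base_envs]
    out = []
    for size in sizes:
        if size > len(remaining):
            continue
        for ext in combinations(remaining, size):
            out.append(CombinationPlan(plan.base_envs, tuple(ext)))
    return out


def masks_per_line(n_envs_total: int, n_base: int) -> int:
    """Number of BLUEs masked per line so that each line retains ``n_base``
    observations: retention n_base / n_envs_total (75/60/50% for 4/5/6
    environments with a 3-environment base)."""
    if n_envs_total < n_base:
        raise ValueError("total environments must be >= base size")
    return n_envs_total - n_base


def _scenario_rng(seed: int, scenario_id: str, replicate_index: int, attempt: int = 0):
    tag = zlib.crc32(scenario_id.encode())
    return np.random.default_rng(
        np.random.SeedSequence(
            entropy=int(seed), spawn_key=(tag, int(replicate_index), attempt)
        )
    )


def generate_mask(
    plan: CombinationPlan,
    line_ids: list[str],
    replicate_index: int,
    seed: int,
    min_lines_per_env: int = 2,
    max_attempts: int = 100,
) -> MaskScenario:
    """Draw one CV2 masking replicate for a plan.

    Each line independently masks a uniformly random subset of
    ``masks_per_line`` environments among all scenario environments (base
    and extension alike). The draw is redrawn (with a derived sub-seed) if
    any environment would retain fewer than ``min_lines_per_env`` lines,
    which keeps the mixed-model equations connected. Deterministic under
    (seed, scenario_id, replicate_index).
    """
    if not plan.extension_envs:
        raise ValueError("plan has no extension environments; nothing to mask")
    n = len(line_ids)
    m = plan.n_envs
    k = masks_per_line(m, len(plan.base_envs))
    if n * (m - k) < min_lines_per_env * m:
        raise ValueError("too few lines to satisfy the connectivity guard")
    for attempt in range(max_attempts):
        rng = _scenario_rng(seed, f"{plan.scenario_id}#rep{replicate_index}", replicate_index, attempt)
        retained = np.ones((n, m), dtype=bool)
        for i in range(n):
            masked = rng.choice(m, size=k, replace=False)
            retained[i, masked] = False
        if (retained.sum(axis=0) >= min_lines_per_env).all():
            return MaskScenario(
                plan=plan,
                replicate_index=replicate_index,
                line_ids=list(line_ids),
                retained=retained,
                seed=seed,
            )
    raise RuntimeError(
        f"could not satisfy the per-environment connectivity guard in "
        f"{max_attempts} attempts"
    )
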