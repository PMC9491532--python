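"""Random-combination benchmark and combinatorial utilities.

The ant-colony short form is judged against the distribution of the same
metrics over uniformly drawn quota-respecting item subsets — the "how good
is optimized vs. lucky" comparison.  ``combination_count`` gives the exact
size of the search space (product of per-domain binomial coefficients),
which is what makes exhaustive search infeasible for realistic pools and
motivates the metaheuristic in the first place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .aco import AcoConfig, CandidateEvaluator
from .simulate import DOMAINS, ItemResponseTable, ScaleMap

__all__ = [
    "random_subsets",
    "summarize_baseline",
    "combination_count",
    "BaselineSummary",
]

_METRICS = ("cfi", "rmsea", "srmr", "adj_r2", "total")


@dataclass
class BaselineSummary:
    n_draws: int
    n_converged: int
    mean: dict[str, float]
    sd: dict[str, float]
    per_draw: pd.DataFrame | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "n_draws": self.n_draws,
            "n_converged": self.n_converged,
            "mean": self.mean,
            "sd": self.sd,
        }


def random_subsets(
    scale_map: ScaleMap,
    quota: int,
    n_draws: int,
    rng: np.random.Generator,
    *,
    item_ids: Sequence[str] | None = None,
) -> np.ndarray:
    """(n_draws, 4*quota) array of uniform quota-respecting subsets.

    Draws are i.i.d., so duplicate subsets can occur — matching naive
    random benchmarking rather than sampling without replacement from the
    space of subsets.  Column indices refer to ``item_ids`` order (default:
    scale-map order), grouped by domain within each row.
    """
    scale_map.check_quota(quota)
    ids = list(scale_map.item_ids if item_ids is None else item_ids)
    dom = scale_map.domain_index(ids)
    pools = [np.where(dom == d)[0] for d in range(len(DOMAINS))]
    out = np.empty((n_draws, quota * len(DOMAINS)), dtype=np.intp)
    for b in range(n_draws):
        out[b] = np.concatenate(
            [np.sort(rng.choice(pool, size=quota, replace=False)) for pool in pools]
        )
    return out


def summarize_baseline(
    subsets: np.ndarray,
    data: ItemResponseTable,
    scale_map: ScaleMap,
    *,
    evaluator: CandidateEvaluator | None = None,
    config: AcoConfig | None = None,
    keep_per_draw: bool = True,
) -> BaselineSummary:
    """Evaluate every subset with the same constrained hierarchical CFA and
    criterion-validity scoring as the colony, and summarize.

    Non-converged draws are excluded from the means/SDs and counted.
    """
    subsets = np.asarray(subsets)
    if subsets.ndim != 2 or subsets.shape[0] < 1:
        raise ValueError("need at least one subset")
    ev = evaluator or CandidateEvaluator(data, scale_map, config)
    m = ev.score_batch(subsets)
    ok = m["converged"]
    if not ok.any():
        raise RuntimeError("all baseline draws failed to converge")
    table = pd.DataFrame({key: m[key] for key in _METRICS + ("converged",)})
    mean = {k: float(table.loc[ok, k].mean()) for k in _METRICS}
    sd = {k: float(table.loc[ok, k].std(ddof=1)) if ok.sum() > 1 else 0.0
          for k in _METRICS}
    return BaselineSummary(
        n_draws=int(subsets.shape[0]),
        n_converged=int(ok.sum()),
        mean=mean,
        sd=sd,
        per_draw=table if keep_per_draw else None,
    )


def combination_count(domain_sizes: Sequence[int], quota: int) -> int:
    """Exact number of quota-respecting subsets: prod_d C(size_d, quota)."""
    total = 1
    for size in domain_sizes:
        if size < quota:
            raise ValueError(f"domain of size {size} cannot supply quota {quota}")
        total *= math.comb(size, quota)
    return total
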