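"""Ant colony optimization for questionnaire short-form selection.

Virtual ants repeatedly assemble candidate short forms (a fixed quota of
items per domain, default 5 from each of the four domains), score each
candidate, and reinforce the items of the iteration's best candidate with
a "pheromone" deposit while all pheromone decays ("evaporation").  Items
with more pheromone are proportionally more likely to be picked by later
ants, steering the colony toward high-scoring combinations.  The run stops
after a configurable number of consecutive iterations without improvement
of the best score (default: 30 ants, patience 20).

A candidate's score is the sum of three logistic transforms ("phi"):

* ``phi_fit``          — mean of phi(CFI) and phi(RMSEA) of the constrained
                         hierarchical CFA (four domain factors, equal
                         higher-order loadings) on the candidate's
                         polychoric submatrix;
* ``phi_reliability``  — mean of phi(minimum domain omega) and
                         phi(minimum first-order loading);
* ``phi_validity``     — phi(adjusted R^2) of the patient/control indicator
                         regressed on the candidate's sum score.

Each phi is 1 / (1 + exp(-direction * (x - center) / scale)), i.e. a soft
pass/fail gate around a target value; the total lies in (0, 3) and a
non-converged CFA scores 0.  The exact transform parameters used in the
original application are not public; the defaults here center each gate on
the conventional quality threshold of its criterion and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import cfa as _cfa
from .polychoric import polychoric_matrix
from .reliability import reliability_report
from .simulate import DOMAINS, ItemResponseTable, ScaleMap
from .validity import adjusted_r2, evaluate_validity

__all__ = [
    "PhiParams",
    "AcoConfig",
    "CandidateScore",
    "PheromoneState",
    "ShortFormResult",
    "phi",
    "CandidateEvaluator",
    "evaluate_candidate",
    "sample_candidate",
    "update_pheromones",
    "run_aco",
]


@dataclass(frozen=True)
class PhiParams:
    """Logistic gate: center (target value), scale (softness), direction."""

    center: float
    scale: float
    direction: int = 1

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("phi scale must be positive")
        if self.direction not in (-1, 1):
            raise ValueError("phi direction must be +1 or -1")


#: gates centered on the conventional quality thresholds of each criterion
DEFAULT_PHI = {
    "cfi": PhiParams(0.95, 0.01, +1),
    "rmsea": PhiParams(0.05, 0.01, -1),
    "omega": PhiParams(0.80, 0.05, +1),
    "min_loading": PhiParams(0.40, 0.05, +1),
    "adj_r2": PhiParams(0.30, 0.05, +1),
}


@dataclass(frozen=True)
class AcoConfig:
    n_ants: int = 30
    patience: int = 20
    evaporation_rate: float = 0.1
    per_domain_quota: int = 5
    phi_params: dict = field(default_factory=lambda: dict(DEFAULT_PHI))
    seed: int = 0
    initial_pheromone: float = 1.0
    pheromone_floor: float = 1e-6
    max_iterations: int = 500

    def __post_init__(self):
        if not (0.0 < self.evaporation_rate < 1.0):
            raise ValueError("evaporation_rate must lie in (0, 1)")
        if self.n_ants < 1 or self.patience < 1 or self.per_domain_quota < 1:
            raise ValueError("n_ants, patience and quota must be positive")


@dataclass
class CandidateScore:
    phi_fit: float
    phi_reliability: float
    phi_validity: float
    total: float
    raw: dict = field(default_factory=dict)  # cfi, rmsea, omega_min, ...
    converged: bool = True

    def to_dict(self) -> dict:
        return {
            "phi_fit": self.phi_fit,
            "phi_reliability": self.phi_reliability,
            "phi_validity": self.phi_validity,
            "total": self.total,
            "converged": self.converged,
            **{f"raw_{k}": v for k, v in self.raw.items()},
        }


@dataclass
class PheromoneState:
    levels: np.ndarray
    iteration: int = 0
    best_subset: np.ndarray | None = None
    best_score: CandidateScore | None = None
    history: list = field(default_factory=list)  # best total per iteration

    @property
    def best_total(self) -> float:
        return -np.inf if self.best_score is None else self.best_score.total


@dataclass
class ShortFormResult:
    item_ids: list[str]
    subset: np.ndarray
    score: CandidateScore
    fit: object  # CfaFit of the winning subset
    reliability: object
    validity: object
    n_iterations: int
    n_evaluations: int
    history: list[float]

    def to_dict(self) -> dict:
        return {
            "item_ids": self.item_ids,
            "score": self.score.to_dict(),
            "fit": self.fit.to_dict(),
            "n_iterations": self.n_iterations,
            "n_evaluations": self.n_evaluations,
            "history": self.history,
        }


def phi(x: float, center: float, scale: float, direction: int = 1):
    """Logistic transform onto (0, 1), monotone in ``direction``."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    return 1.0 / (1.0 + np.exp(-direction * (np.asarray(x, float) - center) / scale))


def _phi_p(x, p: PhiParams):
    return phi(x, p.center, p.scale, p.direction)


class CandidateEvaluator:
    """Shared scoring machinery: polychoric matrix computed once, candidate
    CFAs fitted in batch, results cached by item subset.

    Polychoric correlations are pairwise, so the submatrix of any candidate
    equals its own would-be estimate; computing the full-pool matrix once
    makes candidate evaluation a pure submatrix + small-CFA problem.
    """

    def __init__(
        self,
        table: ItemResponseTable,
        scale_map: ScaleMap,
        config: AcoConfig | None = None,
        *,
        matrix=None,
    ):
        self.table = table
        self.scale_map = scale_map
        self.config = config or AcoConfig()
        self.item_ids = list(table.item_ids)
        self.domain_of = scale_map.domain_index(self.item_ids)
        self.matrix = matrix if matrix is not None else polychoric_matrix(table)
        self.R = self.matrix.rho
        self.n = table.n_respondents
        X = table.responses
        self._X = np.nan_to_num(X, nan=np.nanmean(X))  # MCAR-safe sums
        self._y = table.is_patient().astype(float)
        self._cache: dict[tuple, CandidateScore] = {}
        self.n_evaluations = 0

    # -- batch scoring ----------------------------------------------------
    def score_batch(
        self, subsets: np.ndarray, *, chunk: int = 4096
    ) -> dict[str, np.ndarray]:
        """Raw metrics and phi totals for an array (B, k) of item indices,
        each row ordered by domain.  Large batches are processed in chunks
        to bound the memory of the batched CFA."""
        subsets = np.asarray(subsets)
        if subsets.shape[0] > chunk:
            parts = [
                self.score_batch(subsets[i : i + chunk])
                for i in range(0, subsets.shape[0], chunk)
            ]
            return {
                key: np.concatenate([p[key] for p in parts]) for key in parts[0]
            }
        B, k = subsets.shape
        q = self.config.per_domain_quota
        out = _cfa.fit_shortform_batch(self.R, subsets, self.domain_of, self.n)
        lam, gam = out["lam"], out["gamma"]
        # Schmid-Leiman split, domain-blockwise: (B, 4, q)
        g = (lam * gam[:, None]).reshape(B, len(DOMAINS), q)
        s = (lam * np.sqrt(1.0 - gam[:, None] ** 2)).reshape(B, len(DOMAINS), q)
        theta = np.clip(1.0 - lam**2, 1e-6, None).reshape(B, len(DOMAINS), q)
        cg = g.sum(axis=2) ** 2
        cs = s.sum(axis=2) ** 2
        denom = cg + cs + theta.sum(axis=2)
        omega_domain = (cg + cs) / denom
        omega_min = omega_domain.min(axis=1)
        min_loading = lam.min(axis=1)

        # candidate sum scores via an indicator matrix (BLAS-friendly)
        M = np.zeros((self._X.shape[1], B))
        M[subsets.T, np.arange(B)[None, :]] = 1.0
        scores = self._X @ M  # (n, B)
        y = self._y
        yc = y - y.mean()
        sc = scores - scores.mean(axis=0, keepdims=True)
        denom_r = np.sqrt((sc**2).sum(axis=0) * (yc**2).sum())
        r = (sc * yc[:, None]).sum(axis=0) / np.where(denom_r == 0, np.inf, denom_r)
        n = self.n
        adj = 1.0 - (1.0 - r**2) * (n - 1) / (n - 2)

        pp = self.config.phi_params
        phi_fit = 0.5 * (_phi_p(out["cfi"], pp["cfi"]) + _phi_p(out["rmsea"], pp["rmsea"]))
        phi_rel = 0.5 * (
            _phi_p(omega_min, pp["omega"]) + _phi_p(min_loading, pp["min_loading"])
        )
        phi_val = _phi_p(adj, pp["adj_r2"])
        total = np.where(out["converged"], phi_fit + phi_rel + phi_val, 0.0)
        self.n_evaluations += B
        return {
            "cfi": out["cfi"],
            "rmsea": out["rmsea"],
            "srmr": out["srmr"],
            "chi2": out["chi2"],
            "omega_min": omega_min,
            "min_loading": min_loading,
            "adj_r2": adj,
            "phi_fit": phi_fit,
            "phi_reliability": phi_rel,
            "phi_validity": phi_val,
            "total": total,
            "converged": out["converged"],
        }

    def _score_from_row(self, m: dict, b: int) -> CandidateScore:
        conv = bool(m["converged"][b])
        return CandidateScore(
            phi_fit=float(m["phi_fit"][b]),
            phi_reliability=float(m["phi_reliability"][b]),
            phi_validity=float(m["phi_validity"][b]),
            total=float(m["total"][b]),
            raw={
                key: float(m[key][b])
                for key in ("cfi", "rmsea", "srmr", "omega_min", "min_loading", "adj_r2")
            },
            converged=conv,
        )

    def evaluate_many(self, subsets: Sequence[np.ndarray]) -> list[CandidateScore]:
        """Cached evaluation of a list of candidates (duplicates are free)."""
        keys = [tuple(map(int, s)) for s in subsets]
        todo = [k for k in dict.fromkeys(keys) if k not in self._cache]
        if todo:
            m = self.score_batch(np.array(todo))
            for b, key in enumerate(todo):
                self._cache[key] = self._score_from_row(m, b)
        return [self._cache[k] for k in keys]

    def evaluate(self, subset) -> CandidateScore:
        return self.evaluate_many([np.asarray(subset)])[0]

    def subset_item_ids(self, subset) -> list[str]:
        return [self.item_ids[int(j)] for j in subset]


def evaluate_candidate(
    subset,
    data: ItemResponseTable,
    scale_map: ScaleMap,
    config: AcoConfig | None = None,
    *,
    evaluator: CandidateEvaluator | None = None,
) -> CandidateScore:
    """Score one candidate subset (item ids or column indices).

    Building a :class:`CandidateEvaluator` once and passing it in avoids
    re-estimating the polychoric matrix per call.
    """
    ev = evaluator or CandidateEvaluator(data, scale_map, config)
    subset = np.asarray(subset)
    if subset.dtype.kind in "US":
        subset = np.array([ev.item_ids.index(i) for i in subset])
    q = ev.config.per_domain_quota
    dom = ev.domain_of[subset]
    counts = np.bincount(dom, minlength=len(DOMAINS))
    if not np.all(counts == q):
        raise ValueError(f"candidate must carry exactly {q} items per domain")
    subset = subset[np.argsort(dom, kind="stable")]
    return ev.evaluate(subset)


def sample_candidate(
    state: PheromoneState,
    domain_pools: Sequence[np.ndarray],
    quota: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw quota items per domain without replacement, with probability
    proportional to the current pheromone levels."""
    picks = []
    for pool in domain_pools:
        w = state.levels[pool]
        p = w / w.sum()
        picks.append(np.sort(rng.choice(pool, size=quota, replace=False, p=p)))
    return np.concatenate(picks)


def update_pheromones(
    state: PheromoneState,
    candidates: Sequence[np.ndarray],
    scores: Sequence[CandidateScore],
    config: AcoConfig,
) -> PheromoneState:
    """Evaporate all levels, deposit the iteration-best total on its items."""
    if len(candidates) != len(scores):
        raise ValueError("candidates and scores must align")
    state.levels *= 1.0 - config.evaporation_rate
    if scores:
        best = int(np.argmax([s.total for s in scores]))
        state.levels[np.asarray(candidates[best])] += scores[best].total
    np.clip(state.levels, config.pheromone_floor, None, out=state.levels)
    return state


def run_aco(
    data: ItemResponseTable,
    scale_map: ScaleMap,
    config: AcoConfig | None = None,
    *,
    evaluator: CandidateEvaluator | None = None,
) -> ShortFormResult:
    """Full colony run; returns the best short form found with its complete
    fit, reliability and validity work-up.  Deterministic under a fixed
    ``config.seed``."""
    config = config or AcoConfig()
    scale_map.check_quota(config.per_domain_quota)
    ev = evaluator or CandidateEvaluator(data, scale_map, config)
    if ev.config is not config:
        ev = CandidateEvaluator(data, scale_map, config, matrix=ev.matrix)
    rng = np.random.default_rng(config.seed)
    p = len(ev.item_ids)
    domain_pools = [
        np.where(ev.domain_of == d)[0] for d in range(len(DOMAINS))
    ]
    state = PheromoneState(levels=np.full(p, config.initial_pheromone))
    stall = 0
    while state.iteration < config.max_iterations and stall < config.patience:
        candidates = [
            sample_candidate(state, domain_pools, config.per_domain_quota, rng)
            for _ in range(config.n_ants)
        ]
        scores = ev.evaluate_many(candidates)
        it_best = int(np.argmax([s.total for s in scores]))
        if scores[it_best].total > state.best_total + 1e-9:
            state.best_subset = candidates[it_best].copy()
            state.best_score = scores[it_best]
            stall = 0
        else:
            stall += 1
        update_pheromones(state, candidates, scores, config)
        state.iteration += 1
        state.history.append(state.best_total)

    if state.best_subset is None or not state.best_score.converged:
        raise RuntimeError("no converged candidate found within the iteration budget")

    winner_ids = ev.subset_item_ids(state.best_subset)
    spec = _cfa.build_model("shortform", scale_map, item_ids=winner_ids)
    sub = ev.matrix.submatrix(winner_ids)
    fit = _cfa.fit_cfa(sub, spec, n=ev.n)
    rel = reliability_report(ev.matrix, fit, scale_map)
    val = evaluate_validity(data, winner_ids)
    return ShortFormResult(
        item_ids=winner_ids,
        subset=state.best_subset,
        score=state.best_score,
        fit=fit,
        reliability=rel,
        validity=val,
        n_iterations=state.iteration,
        n_evaluations=ev.n_evaluations,
        history=state.history,
    )
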