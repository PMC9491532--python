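"""Synthetic ordinal item-response data with a known latent structure.

This module generates respondent × item tables of 5-point ordinal responses
(0..4) that emulate a multi-domain personality-functioning questionnaire:
97 items grouped into four domains (Identity, Self-direction, Empathy,
Intimacy), each domain split into two subscales, answered by a healthy
control group and a patient group whose general-severity factor is shifted
upward by a configurable effect size ``group_shift`` (standardized units).

The data-generating process is a standard latent-response model: each item
has a continuous latent variable built from common factors plus unique
noise with unit total variance, and the observed ordinal category is the
number of item thresholds lying below the latent value.  Two structures are
supported:

``bifactor``
    latent_i = g_i * G + s_i * S_d(i) + sqrt(1 - g_i^2 - s_i^2) * e_i
    with the general factor G and the four specific factors mutually
    orthogonal.

``hierarchical``
    F_d = gamma_d * G + sqrt(1 - gamma_d^2) * u_d
    latent_i = lambda_i * F_d(i) + sqrt(1 - lambda_i^2) * e_i
    i.e. first-order domain factors whose correlation is carried entirely
    by a second-order general factor with per-domain paths gamma_d.

For the patient group the general factor G has mean ``group_shift`` instead
of 0; everything else is shared, so the group separation of any sum score
is governed by the loadings alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DOMAINS = ("Identity", "Self-direction", "Empathy", "Intimacy")

__all__ = [
    "DOMAINS",
    "ScaleMap",
    "TrueModel",
    "ItemResponseTable",
    "make_default_scale_map",
    "make_default_true_model",
    "simulate_responses",
    "implied_latent_correlation",
]


class QuotaInfeasibleError(ValueError):
    """A domain holds fewer items than the per-domain selection quota."""


class GenerationError(RuntimeError):
    """The model's implied correlation matrix is not positive semi-definite."""


@dataclass(frozen=True)
class ScaleMap:
    """Assignment of each item to one of four domains and one of two subscales.

    Parameters
    ----------
    assignments:
        Mapping from item id to ``(domain, subscale)`` with domain one of
        :data:`DOMAINS` and subscale in {1, 2}.
    """

    assignments: Mapping[str, tuple[str, int]]

    def __post_init__(self) -> None:
        for item, (domain, sub) in self.assignments.items():
            if domain not in DOMAINS:
                raise ValueError(f"unknown domain {domain!r} for item {item!r}")
            if sub not in (1, 2):
                raise ValueError(f"subscale must be 1 or 2, got {sub!r}")
        present = {d for d, _ in self.assignments.values()}
        if present != set(DOMAINS):
            raise ValueError(f"scale map must cover all four domains, has {sorted(present)}")

    @property
    def item_ids(self) -> list[str]:
        return list(self.assignments)

    @property
    def n_items(self) -> int:
        return len(self.assignments)

    def domain_of(self, item_id: str) -> str:
        return self.assignments[item_id][0]

    def items_in(self, domain: str) -> list[str]:
        return [i for i, (d, _) in self.assignments.items() if d == domain]

    def domain_index(self, item_ids: Sequence[str] | None = None) -> np.ndarray:
        """Integer domain code (index into DOMAINS) per item, in table order."""
        ids = self.item_ids if item_ids is None else list(item_ids)
        lookup = {d: k for k, d in enumerate(DOMAINS)}
        return np.array([lookup[self.assignments[i][0]] for i in ids], dtype=np.intp)

    def check_quota(self, quota: int) -> None:
        for d in DOMAINS:
            n = len(self.items_in(d))
            if n < quota:
                raise QuotaInfeasibleError(
                    f"domain {d!r} has {n} items, fewer than quota {quota}"
                )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"item_id": i, "domain": d, "subscale": s}
            for i, (d, s) in self.assignments.items()
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ScaleMap":
        return cls(
            {
                str(r.item_id): (str(r.domain), int(r.subscale))
                for r in df.itertuples(index=False)
            }
        )

    @classmethod
    def from_csv(cls, path) -> "ScaleMap":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class TrueModel:
    """Data-generating latent model for ordinal item responses.

    ``general_loadings`` are the per-item loadings on the general factor for
    the bifactor structure, or the first-order loadings on the item's domain
    factor for the hierarchical structure.  ``specific_loadings`` are used by
    the bifactor structure only; ``higher_order_loadings`` (one per domain)
    by the hierarchical structure only.
    """

    scale_map: ScaleMap
    structure: str  # "bifactor" | "hierarchical"
    general_loadings: np.ndarray
    specific_loadings: np.ndarray
    thresholds: np.ndarray  # (p, 4), strictly increasing rows
    group_shift: float = 2.1
    higher_order_loadings: np.ndarray | None = None  # (4,) hierarchical only

    def __post_init__(self) -> None:
        p = self.scale_map.n_items
        self.general_loadings = np.asarray(self.general_loadings, dtype=float)
        self.specific_loadings = np.asarray(self.specific_loadings, dtype=float)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.structure not in ("bifactor", "hierarchical"):
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.general_loadings.shape != (p,) or self.specific_loadings.shape != (p,):
            raise ValueError("loading vectors must have one entry per item")
        if self.thresholds.shape != (p, 4):
            raise ValueError("thresholds must be (n_items, 4)")
        if np.any(np.diff(self.thresholds, axis=1) <= 0):
            raise ValueError("thresholds must be strictly increasing per item")
        if self.structure == "hierarchical":
            if self.higher_order_loadings is None:
                raise ValueError("hierarchical structure requires higher_order_loadings")
            self.higher_order_loadings = np.asarray(self.higher_order_loadings, float)
            if self.higher_order_loadings.shape != (len(DOMAINS),):
                raise ValueError("need one higher-order loading per domain")
            if np.any(np.abs(self.higher_order_loadings) >= 1):
                raise ValueError("higher-order loadings must lie in (-1, 1)")
        communality = self.general_loadings**2
        if self.structure == "bifactor":
            communality = communality + self.specific_loadings**2
        if np.any(communality >= 1):
            raise ValueError("item communality must stay below 1")

    @property
    def n_items(self) -> int:
        return self.scale_map.n_items

    def to_json(self, path) -> None:
        payload = {
            "structure": self.structure,
            "group_shift": self.group_shift,
            "general_loadings": self.general_loadings.tolist(),
            "specific_loadings": self.specific_loadings.tolist(),
            "higher_order_loadings": (
                None
                if self.higher_order_loadings is None
                else self.higher_order_loadings.tolist()
            ),
            "thresholds": self.thresholds.tolist(),
            "scale_map": {
                i: list(v) for i, v in self.scale_map.assignments.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TrueModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            scale_map=ScaleMap(
                {i: (d, int(s)) for i, (d, s) in payload["scale_map"].items()}
            ),
            structure=payload["structure"],
            general_loadings=np.array(payload["general_loadings"]),
            specific_loadings=np.array(payload["specific_loadings"]),
            thresholds=np.array(payload["thresholds"]),
            group_shift=payload["group_shift"],
            higher_order_loadings=(
                None
                if payload["higher_order_loadings"] is None
                else np.array(payload["higher_order_loadings"])
            ),
        )


@dataclass
class ItemResponseTable:
    """Respondents × items table of ordinal responses with group labels.

    ``responses`` is float so that missing entries can be ``NaN``; observed
    entries are whole numbers in {0, 1, 2, 3, 4}.
    """

    responses: np.ndarray
    group: np.ndarray  # "control" | "patient" per respondent
    respondent_ids: list[str] = field(default_factory=list)
    item_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        self.group = np.asarray(self.group, dtype=object)
        n, p = self.responses.shape
        if not self.respondent_ids:
            self.respondent_ids = [f"r{k:04d}" for k in range(n)]
        if not self.item_ids:
            self.item_ids = [f"item_{k + 1:03d}" for k in range(p)]
        if len(self.group) != n:
            raise ValueError("one group label per respondent required")
        observed = self.responses[~np.isnan(self.responses)]
        if observed.size and (
            np.any(observed != np.round(observed))
            or observed.min() < 0
            or observed.max() > 4
        ):
            raise ValueError("responses must be integers in {0..4} or NaN")
        bad = set(self.group) - {"control", "patient"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    @property
    def n_respondents(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    def is_patient(self) -> np.ndarray:
        return np.asarray(self.group == "patient")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.responses, columns=self.item_ids)
        df.insert(0, "group", self.group)
        df.insert(0, "respondent_id", self.respondent_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ItemResponseTable":
        items = [c for c in df.columns if c not in ("respondent_id", "group")]
        return cls(
            responses=df[items].to_numpy(dtype=float),
            group=df["group"].to_numpy(),
            respondent_ids=[str(x) for x in df["respondent_id"]],
            item_ids=list(items),
        )

    @classmethod
    def from_csv(cls, path) -> "ItemResponseTable":
        return cls.from_frame(pd.read_csv(path))


def make_default_scale_map(
    n_items_per_domain: Sequence[int] = (25, 24, 24, 24),
) -> ScaleMap:
    """Build a scale map with the given item counts, two subscales per domain.

    The default 25/24/24/24 split reproduces a 97-item instrument; the true
    per-domain composition of the original questionnaire is not public, so
    the counts are configurable.
    """
    if len(n_items_per_domain) != len(DOMAINS):
        raise ValueError("need one item count per domain")
    assignments: dict[str, tuple[str, int]] = {}
    k = 0
    for domain, count in zip(DOMAINS, n_items_per_domain):
        for j in range(count):
            k += 1
            assignments[f"item_{k:03d}"] = (domain, 1 if j < count // 2 else 2)
    return ScaleMap(assignments)


def make_default_true_model(
    n_items_per_domain: Sequence[int] = (25, 24, 24, 24),
    structure: str = "hierarchical",
    seed: int | np.random.SeedSequence | None = 0,
    *,
    quota: int = 5,
    general_range: tuple[float, float] = (0.5, 0.8),
    specific_range: tuple[float, float] = (0.2, 0.5),
    higher_order_range: tuple[float, float] = (0.5, 0.8),
    group_shift: float = 2.1,
    threshold_quantiles: Sequence[float] = (0.5, 0.75, 0.9, 0.97),
    threshold_jitter: float = 0.1,
) -> TrueModel:
    """Draw a plausible generating model for the default study conditions.

    Loadings are drawn uniformly from the configured ranges.  Thresholds are
    the standard-normal quantiles of ``threshold_quantiles`` (right-skewed in
    the control group: most healthy respondents endorse the low categories of
    a pathology item) plus a small per-item jitter, kept strictly increasing.
    ``group_shift`` defaults to 2.1 standardized units, the long-form
    patient–control separation the instrument was built to achieve.
    """
    for count in n_items_per_domain:
        if count < quota:
            raise QuotaInfeasibleError(
                f"domain with {count} items cannot supply quota {quota}"
            )
    rng = np.random.default_rng(seed)
    scale_map = make_default_scale_map(n_items_per_domain)
    p = scale_map.n_items
    from scipy.stats import norm

    general = rng.uniform(*general_range, size=p)
    specific = (
        rng.uniform(*specific_range, size=p)
        if structure == "bifactor"
        else np.zeros(p)
    )
    higher = (
        rng.uniform(*higher_order_range, size=len(DOMAINS))
        if structure == "hierarchical"
        else None
    )
    base = norm.ppf(np.asarray(threshold_quantiles, dtype=float))
    thr = base[None, :] + rng.uniform(-threshold_jitter, threshold_jitter, size=(p, 4))
    thr = np.sort(thr, axis=1)
    # enforce strict increase in the unlikely event jitter produced a tie
    thr += np.arange(4)[None, :] * 1e-9
    return TrueModel(
        scale_map=scale_map,
        structure=structure,
        general_loadings=general,
        specific_loadings=specific,
        thresholds=thr,
        group_shift=group_shift,
        higher_order_loadings=higher,
    )


def implied_latent_correlation(model: TrueModel) -> np.ndarray:
    """Exact model-implied correlation matrix of the continuous latent responses.

    Bifactor:      rho_ij = g_i g_j + [d(i)=d(j)] s_i s_j
    Hierarchical:  rho_ij = lam_i lam_j              (same domain)
                   rho_ij = lam_i gam_d(i) gam_d(j) lam_j   (cross-domain)
    """
    d = model.scale_map.domain_index()
    same = d[:, None] == d[None, :]
    if model.structure == "bifactor":
        g = model.general_loadings
        s = model.specific_loadings
        rho = np.outer(g, g) + same * np.outer(s, s)
    else:
        lam = model.general_loadings
        gam = model.higher_order_loadings[d]
        lg = lam * gam
        rho = np.where(same, np.outer(lam, lam), np.outer(lg, lg))
    np.fill_diagonal(rho, 1.0)
    return rho


def simulate_responses(
    model: TrueModel,
    n_control: int,
    n_patient: int,
    seed: int | np.random.SeedSequence | None = 0,
    *,
    missing_rate: float = 0.0,
) -> ItemResponseTable:
    """Simulate ordinal responses for a control and a patient sample.

    Latent factors are standard normal; patients' general factor mean is
    shifted by ``model.group_shift``.  The observed category is the count of
    item thresholds below the continuous latent response.  With
    ``missing_rate`` > 0 a missing-completely-at-random mask is applied.
    """
    if n_control < 0 or n_patient < 0:
        raise ValueError("group sizes must be non-negative")
    rho = implied_latent_correlation(model)
    if np.linalg.eigvalsh(rho).min() < -1e-10:
        raise GenerationError("implied latent correlation is not PSD")
    rng = np.random.default_rng(seed)
    n = n_control + n_patient
    p = model.n_items
    d = model.scale_map.domain_index()
    is_patient = np.zeros(n, dtype=bool)
    is_patient[n_control:] = True

    g_factor = rng.standard_normal(n) + model.group_shift * is_patient
    domain_factors = rng.standard_normal((n, len(DOMAINS)))
    unique = rng.standard_normal((n, p))

    if model.structure == "bifactor":
        g, s = model.general_loadings, model.specific_loadings
        uniq_sd = np.sqrt(1.0 - g**2 - s**2)
        latent = (
            g_factor[:, None] * g[None, :]
            + domain_factors[:, d] * s[None, :]
            + unique * uniq_sd[None, :]
        )
    else:
        lam = model.general_loadings
        gam = model.higher_order_loadings
        first_order = (
            g_factor[:, None] * gam[None, :]
            + domain_factors * np.sqrt(1.0 - gam**2)[None, :]
        )
        uniq_sd = np.sqrt(1.0 - lam**2)
        latent = first_order[:, d] * lam[None, :] + unique * uniq_sd[None, :]

    responses = (latent[:, :, None] > model.thresholds[None, :, :]).sum(axis=2)
    responses = responses.astype(float)
    if missing_rate > 0:
        mask = rng.random((n, p)) < missing_rate
        responses[mask] = np.nan
    group = np.where(is_patient, "patient", "control").astype(object)
    return ItemResponseTable(
        responses=responses, group=group, item_ids=model.scale_map.item_ids
    )
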