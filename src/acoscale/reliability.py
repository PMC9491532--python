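"""Reliability coefficients: ordinal alpha and model-based omegas.

Ordinal alpha is coefficient alpha evaluated on the polychoric rather than
the Pearson correlation matrix; because the polychoric matrix is in the
correlation metric this is the standardized-alpha formula

    alpha = k * rbar / (1 + (k - 1) * rbar)

with rbar the mean off-diagonal polychoric correlation of the k items.

Omega coefficients partition the common variance of a sum score.  For a
bifactor solution with general loadings g_i, specific loadings s_i and
unique variances theta_i = 1 - g_i^2 - s_i^2 (standardized items):

    omega_total = ((sum g)^2 + sum_f (sum_f s)^2) / (... + sum theta)
    omega_h     = (sum g)^2 / same denominator           (total score)
    omega_hs    = (sum_d s)^2 / domain-scale denominator (domain score)

where for a domain score the general factor's contribution counts as
variance the specific factor cannot claim.  Higher-order solutions are
first transformed to an equivalent bifactor pattern (Schmid-Leiman):
g_i = lambda_i * gamma_d(i), s_i = lambda_i * sqrt(1 - gamma_d(i)^2),
after which the same formulas apply.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cfa import CfaFit
from .polychoric import PolychoricMatrix
from .simulate import DOMAINS

__all__ = [
    "ordinal_alpha",
    "omega_from_loadings",
    "omega_from_bifactor",
    "omega_from_hierarchical",
    "schmid_leiman",
    "ReliabilityReport",
    "reliability_report",
]


class WrongStructureError(TypeError):
    """Omega routine called on a fit with an incompatible factor structure."""


def ordinal_alpha(rho, items=None) -> float:
    """Standardized coefficient alpha on a polychoric (sub)matrix.

    ``rho`` may be a PolychoricMatrix or a plain correlation ndarray;
    ``items`` optionally selects a subscale by item id (PolychoricMatrix)
    or integer index.
    """
    if isinstance(rho, PolychoricMatrix):
        R = rho.submatrix(items).rho if items is not None else rho.rho
    else:
        R = np.asarray(rho, dtype=float)
        if items is not None:
            idx = np.asarray(items)
            R = R[np.ix_(idx, idx)]
    k = R.shape[0]
    if k < 2:
        raise ValueError("alpha needs at least 2 items")
    off = R[np.triu_indices(k, 1)]
    if not np.all(np.isfinite(off)):
        raise ValueError("degenerate submatrix: non-finite correlations")
    rbar = off.mean()
    return float(k * rbar / (1.0 + (k - 1) * rbar))


def omega_from_loadings(
    g: np.ndarray, s: np.ndarray, factor_of_item: np.ndarray, scale=None
) -> tuple[float, float]:
    """(omega_total, omega_hierarchical) from a bifactor loading pattern.

    ``scale=None`` gives the total score (omega_hierarchical = OmegaH);
    ``scale=f`` restricts to the items of specific factor ``f`` and returns
    OmegaHS, the share of the domain-score variance owned by the specific
    factor beyond the general one.
    """
    g = np.asarray(g, float)
    s = np.asarray(s, float)
    f = np.asarray(factor_of_item)
    theta = np.clip(1.0 - g**2 - s**2, 1e-6, None)
    if scale is None:
        common_general = g.sum() ** 2
        common_specific = sum(
            s[f == lab].sum() ** 2 for lab in np.unique(f)
        )
        denom = common_general + common_specific + theta.sum()
        return (
            float((common_general + common_specific) / denom),
            float(common_general / denom),
        )
    sel = f == scale
    if not np.any(sel):
        raise ValueError(f"no items on factor {scale!r}")
    cg = g[sel].sum() ** 2
    cs = s[sel].sum() ** 2
    denom = cg + cs + theta[sel].sum()
    return float((cg + cs) / denom), float(cs / denom)


def omega_from_bifactor(fit: CfaFit, scale=None) -> tuple[float, float]:
    """Omegas straight from a bifactor fit (models 4/5), or a one-factor fit
    treated as the degenerate bifactor with all specific loadings zero."""
    if not (fit.converged and fit.identified):
        raise ValueError("omega requires a converged, identified fit")
    if fit.spec.family == "bifactor":
        g, s = fit.loadings, fit.specific_loadings
        f = fit.spec.factor_of_item
    elif fit.spec.family == "correlated" and fit.spec.n_factors == 1:
        g = fit.loadings
        s = np.zeros_like(g)
        f = fit.spec.factor_of_item
    else:
        raise WrongStructureError(
            f"model {fit.spec.model_id!r} has no bifactor structure"
        )
    return omega_from_loadings(g, s, f, scale)


def schmid_leiman(
    first_order: np.ndarray, higher_order: np.ndarray, factor_of_item: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Residualize a higher-order solution into bifactor-form loadings."""
    lam = np.asarray(first_order, float)
    gam = np.asarray(higher_order, float)
    f = np.asarray(factor_of_item)
    g = lam * gam[f]
    s = lam * np.sqrt(1.0 - gam[f] ** 2)
    return g, s


def omega_from_hierarchical(fit: CfaFit, scale=None) -> tuple[float, float]:
    """Omegas from a higher-order fit via the Schmid-Leiman decomposition."""
    if not (fit.converged and fit.identified):
        raise ValueError("omega requires a converged, identified fit")
    if fit.spec.family != "hierarchical":
        raise WrongStructureError(
            f"model {fit.spec.model_id!r} is not a higher-order model"
        )
    g, s = schmid_leiman(
        fit.loadings, fit.higher_order_loadings, fit.spec.factor_of_item
    )
    return omega_from_loadings(g, s, fit.spec.factor_of_item, scale)


def _omega_dispatch(fit: CfaFit, scale=None):
    if fit.spec.family == "hierarchical":
        return omega_from_hierarchical(fit, scale)
    return omega_from_bifactor(fit, scale)


@dataclass
class ReliabilityReport:
    """Per-scale ordinal alpha and omegas for one fitted model."""

    model_id: str
    ordinal_alpha: dict[str, float]
    omega_total: dict[str, float]
    omega_hierarchical: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        scales = ["Total", *DOMAINS]
        return pd.DataFrame(
            {
                "ordinal_alpha": [self.ordinal_alpha.get(s, np.nan) for s in scales],
                "omega_total": [self.omega_total.get(s, np.nan) for s in scales],
                "omega_hierarchical": [
                    self.omega_hierarchical.get(s, np.nan) for s in scales
                ],
            },
            index=scales,
        )


def reliability_report(
    matrix: PolychoricMatrix, fit: CfaFit, scale_map
) -> ReliabilityReport:
    """Alpha for every scale plus model-based omegas where the structure
    provides a general/specific partition.

    Ordinal alpha depends only on the polychoric matrix; omegas come from
    the fitted model.  For correlated-factor models with more than one
    factor no general factor exists, so omegas are reported as NaN.
    """
    item_ids = list(fit.spec.item_ids)
    alpha = {"Total": ordinal_alpha(matrix.submatrix(item_ids).rho)}
    for d in DOMAINS:
        members = [i for i in item_ids if scale_map.domain_of(i) == d]
        if len(members) >= 2:
            alpha[d] = ordinal_alpha(matrix.submatrix(members).rho)

    omega_t: dict[str, float] = {}
    omega_h: dict[str, float] = {}
    supports_omega = fit.spec.family in ("bifactor", "hierarchical") or (
        fit.spec.family == "correlated" and fit.spec.n_factors == 1
    )
    if supports_omega and fit.converged and fit.identified:
        omega_t["Total"], omega_h["Total"] = _omega_dispatch(fit, None)
        # map each domain to its factor index within this model
        for d in DOMAINS:
            members = [
                k for k, i in enumerate(item_ids) if scale_map.domain_of(i) == d
            ]
            if not members:
                continue
            fac = np.unique(fit.spec.factor_of_item[members])
            if fac.size != 1:
                continue  # domain split across factors: no domain-level omega
            if fit.spec.n_factors == 1:
                continue
            omega_t[d], omega_h[d] = _omega_dispatch(fit, int(fac[0]))
    return ReliabilityReport(
        model_id=fit.spec.model_id,
        ordinal_alpha=alpha,
        omega_total=omega_t,
        omega_hierarchical=omega_h,
    )
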