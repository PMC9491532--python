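"""Confirmatory factor models for ordinal items, fitted on polychoric matrices.

Nine competing configurations of a multi-domain questionnaire are supported,
identified by the ids used throughout the package:

====  =========================================================
id    structure
====  =========================================================
1     one common factor on all items
2     two correlated factors (self / interpersonal areas)
3     four correlated domain factors
4     bifactor: general + two orthogonal area-specific factors
5     bifactor: general + four orthogonal domain-specific factors
6a    two first-order area factors + second-order factor,
      higher-order loadings free (not identified by design)
6b    as 6a with the two higher-order loadings constrained equal
7a    four first-order domain factors + second-order factor
7b    as 7a with all four higher-order loadings constrained equal
shortform  7b on a selected item subset
====  =========================================================

Fitting minimizes the (diagonally weighted) least-squares discrepancy

    F(theta) = sum_{i<j} w_ij (r_ij - sigma_ij(theta))^2

between the sample polychoric correlations and the model-implied
correlations, with unit weights by default (ULS).  The chi-square statistic
uses the convention chi2 = (n - 1) * F_min; no robust mean-and-variance
scaling is applied, so absolute chi-square values are not comparable to
WLSMV output even though the relative ordering of models is.

Identification is checked numerically: a rank-deficient Jacobian of the
implied moments at the solution (smallest singular value below tolerance)
flags the fit as not identified, mirroring the classic failure of a
two-indicator higher-order factor with free loadings (model 6a).

Parameter counts follow the ordinal-data convention that each item
contributes its 4 estimated thresholds in addition to the structural
parameters, so ``n_par`` is comparable to standard categorical-SEM output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .polychoric import PolychoricMatrix
from .simulate import DOMAINS, ScaleMap

__all__ = [
    "MODEL_IDS",
    "CfaModelSpec",
    "CfaFit",
    "build_model",
    "fit_cfa",
    "fit_indices",
    "classify_fit",
    "fit_shortform_batch",
]

MODEL_IDS = ("1", "2", "3", "4", "5", "6a", "6b", "7a", "7b", "shortform")

#: broad functioning areas: self-related vs interpersonal
_AREA_OF_DOMAIN = {
    "Identity": 0,
    "Self-direction": 0,
    "Empathy": 1,
    "Intimacy": 1,
}

_THRESHOLDS_PER_ITEM = 4


class NotIdentifiedError(RuntimeError):
    pass


@dataclass(frozen=True)
class CfaModelSpec:
    """Structural specification of one factor configuration."""

    model_id: str
    family: str  # "correlated" | "bifactor" | "hierarchical"
    item_ids: tuple[str, ...]
    factor_of_item: np.ndarray  # first-order / specific factor index per item
    n_factors: int  # number of first-order (or specific) factors
    equal_higher_order: bool = False  # hierarchical only
    description: str = ""

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    @property
    def n_free_structural(self) -> int:
        p, m = self.n_items, self.n_factors
        if self.family == "correlated":
            return p + m * (m - 1) // 2
        if self.family == "bifactor":
            return 2 * p
        # hierarchical
        return p + (1 if self.equal_higher_order else m)

    @property
    def n_par(self) -> int:
        """Estimated parameters including per-item thresholds."""
        return self.n_items * _THRESHOLDS_PER_ITEM + self.n_free_structural

    @property
    def df(self) -> int:
        p = self.n_items
        return p * (p - 1) // 2 - self.n_free_structural

    @property
    def has_equality_constraint(self) -> bool:
        return self.family == "hierarchical" and self.equal_higher_order


def build_model(
    model_id: str, scale_map: ScaleMap, item_ids: Sequence[str] | None = None
) -> CfaModelSpec:
    """Construct the requested factor configuration over the given items."""
    model_id = str(model_id)
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}; expected one of {MODEL_IDS}")
    ids = tuple(scale_map.item_ids if item_ids is None else item_ids)
    domain_idx = scale_map.domain_index(ids)
    area_idx = np.array(
        [_AREA_OF_DOMAIN[scale_map.domain_of(i)] for i in ids], dtype=np.intp
    )

    if model_id == "1":
        return CfaModelSpec(
            model_id, "correlated", ids, np.zeros(len(ids), np.intp), 1,
            description="one common severity factor",
        )
    if model_id == "2":
        return CfaModelSpec(
            model_id, "correlated", ids, area_idx, 2,
            description="correlated self / interpersonal factors",
        )
    if model_id == "3":
        return CfaModelSpec(
            model_id, "correlated", ids, domain_idx, 4,
            description="four correlated domain factors",
        )
    if model_id == "4":
        return CfaModelSpec(
            model_id, "bifactor", ids, area_idx, 2,
            description="general + two orthogonal area specifics",
        )
    if model_id == "5":
        return CfaModelSpec(
            model_id, "bifactor", ids, domain_idx, 4,
            description="general + four orthogonal domain specifics",
        )
    if model_id in ("6a", "6b"):
        return CfaModelSpec(
            model_id, "hierarchical", ids, area_idx, 2,
            equal_higher_order=(model_id == "6b"),
            description="two area factors under a second-order factor",
        )
    if model_id in ("7a", "7b"):
        return CfaModelSpec(
            model_id, "hierarchical", ids, domain_idx, 4,
            equal_higher_order=(model_id == "7b"),
            description="four domain factors under a second-order factor",
        )
    # shortform: 7b structure with the equal-loading constraint, on a subset
    return CfaModelSpec(
        "shortform", "hierarchical", ids, domain_idx, 4,
        equal_higher_order=True,
        description="four domain factors, equal higher-order loadings",
    )


@dataclass
class CfaFit:
    """Result of fitting one configuration to a polychoric matrix."""

    spec: CfaModelSpec
    theta: np.ndarray
    f_min: float
    chi_square: float
    df: int
    n_par: int
    cfi: float
    rmsea: float
    srmr: float
    n: int
    converged: bool
    identified: bool
    heywood: bool = False
    n_restarts_used: int = 0
    min_singular_ratio: float = np.nan
    residuals: np.ndarray | None = None

    # --- parameter views -------------------------------------------------
    @property
    def loadings(self) -> np.ndarray:
        """Primary standardized loadings (general for bifactor, first-order
        otherwise)."""
        p = self.spec.n_items
        return self.theta[:p]

    @property
    def specific_loadings(self) -> np.ndarray:
        if self.spec.family != "bifactor":
            raise AttributeError("specific loadings exist only for bifactor fits")
        p = self.spec.n_items
        return self.theta[p : 2 * p]

    @property
    def factor_correlations(self) -> np.ndarray:
        if self.spec.family != "correlated":
            raise AttributeError("factor correlations exist only for correlated fits")
        m = self.spec.n_factors
        phi = np.eye(m)
        vals = self.theta[self.spec.n_items :]
        iu = np.triu_indices(m, 1)
        phi[iu] = vals
        phi[(iu[1], iu[0])] = vals
        return phi

    @property
    def higher_order_loadings(self) -> np.ndarray:
        """Per-factor second-order loadings (broadcast if constrained equal)."""
        if self.spec.family != "hierarchical":
            raise AttributeError("higher-order loadings exist only for hierarchical fits")
        vals = self.theta[self.spec.n_items :]
        if self.spec.equal_higher_order:
            return np.full(self.spec.n_factors, vals[0])
        return vals

    def to_dict(self) -> dict:
        out = {
            "model_id": self.spec.model_id,
            "n_items": self.spec.n_items,
            "n_par": self.n_par,
            "df": self.df,
            "chi_square": self.chi_square,
            "cfi": self.cfi,
            "rmsea": self.rmsea,
            "srmr": self.srmr,
            "converged": self.converged,
            "identified": self.identified,
            "heywood": self.heywood,
            "loadings": self.loadings.tolist(),
        }
        if self.spec.family == "hierarchical":
            out["higher_order_loadings"] = self.higher_order_loadings.tolist()
        if self.spec.family == "bifactor":
            out["specific_loadings"] = self.specific_loadings.tolist()
        if self.spec.family == "correlated":
            out["factor_correlations"] = self.factor_correlations.tolist()
        return out


# ---------------------------------------------------------------------------
# implied moments and Jacobians (off-diagonal elements only; the diagonal is
# fixed at 1 in the correlation metric, so residual variances are implied)
# ---------------------------------------------------------------------------


def _sigma_jac(spec: CfaModelSpec, theta: np.ndarray, iu: tuple):
    p = spec.n_items
    f = spec.factor_of_item
    i, j = iu
    P = i.size
    if spec.family == "bifactor":
        g, s = theta[:p], theta[p:]
        same = f[i] == f[j]
        sigma = g[i] * g[j] + same * s[i] * s[j]
        J = np.zeros((P, 2 * p))
        rows = np.arange(P)
        np.add.at(J, (rows, i), g[j])
        np.add.at(J, (rows, j), g[i])
        np.add.at(J, (rows, p + i), same * s[j])
        np.add.at(J, (rows, p + j), same * s[i])
        return sigma, J
    if spec.family == "correlated":
        m = spec.n_factors
        lam = theta[:p]
        phi = np.eye(m)
        iu_m = np.triu_indices(m, 1)
        phi[iu_m] = theta[p:]
        phi[(iu_m[1], iu_m[0])] = theta[p:]
        w = phi[f[i], f[j]]
        sigma = lam[i] * lam[j] * w
        J = np.zeros((P, p + m * (m - 1) // 2))
        rows = np.arange(P)
        np.add.at(J, (rows, i), lam[j] * w)
        np.add.at(J, (rows, j), lam[i] * w)
        pair_code = {
            (a, b): k for k, (a, b) in enumerate(zip(*iu_m))
        }
        for (a, b), k in pair_code.items():
            mask = ((f[i] == a) & (f[j] == b)) | ((f[i] == b) & (f[j] == a))
            J[mask, p + k] = lam[i[mask]] * lam[j[mask]]
        return sigma, J
    # hierarchical
    m = spec.n_factors
    lam = theta[:p]
    if spec.equal_higher_order:
        gam = np.full(m, theta[p])
    else:
        gam = theta[p:]
    same = f[i] == f[j]
    w = np.where(same, 1.0, gam[f[i]] * gam[f[j]])
    sigma = lam[i] * lam[j] * w
    n_g = 1 if spec.equal_higher_order else m
    J = np.zeros((P, p + n_g))
    rows = np.arange(P)
    np.add.at(J, (rows, i), lam[j] * w)
    np.add.at(J, (rows, j), lam[i] * w)
    cross = ~same
    ll = lam[i] * lam[j]
    if spec.equal_higher_order:
        J[cross, p] = ll[cross] * 2.0 * gam[0]
    else:
        for a in range(m):
            hit_i = cross & (f[i] == a)
            hit_j = cross & (f[j] == a)
            J[hit_i, p + a] += ll[hit_i] * gam[f[j][hit_i]]
            J[hit_j, p + a] += ll[hit_j] * gam[f[i][hit_j]]
    return sigma, J


def _start_values(spec: CfaModelSpec) -> np.ndarray:
    # deterministic start: all loadings 0.5, all paths/correlations 0.5
    return np.full(spec.n_free_structural, 0.5)


_LOADING_BOUND = 0.999


def _clip_theta(spec: CfaModelSpec, theta: np.ndarray) -> np.ndarray:
    theta = np.clip(theta, -_LOADING_BOUND, _LOADING_BOUND)
    if spec.family == "bifactor":
        p = spec.n_items
        g, s = theta[:p], theta[p:]
        comm = g**2 + s**2
        over = comm > 1.0 - 1e-6
        if np.any(over):
            scale = np.sqrt((1.0 - 1e-6) / comm[over])
            theta = theta.copy()
            theta[:p][over] = g[over] * scale
            theta[p:][over] = s[over] * scale
    return theta


def fit_cfa(
    matrix,
    spec: CfaModelSpec,
    n: int,
    weight: str = "ULS",
    *,
    dwls_weights: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 300,
    n_restarts: int = 5,
    keep_residuals: bool = False,
) -> CfaFit:
    """Fit one configuration by damped Gauss-Newton on the LS discrepancy.

    ``matrix`` is a :class:`PolychoricMatrix` or a plain correlation ndarray.
    ``weight='DWLS'`` applies the per-element weights in ``dwls_weights``
    (same length as the vector of unique off-diagonal moments); with unit
    weights DWLS coincides with ULS, which is the default since the
    asymptotic covariance of the polychoric estimates is out of scope here.
    """
    R = matrix.rho if isinstance(matrix, PolychoricMatrix) else np.asarray(matrix)
    p = spec.n_items
    if R.shape != (p, p):
        raise ValueError("matrix size does not match model spec")
    iu = np.triu_indices(p, 1)
    r_obs = R[iu]
    if weight.upper() == "ULS" or dwls_weights is None:
        w = np.ones_like(r_obs)
    else:
        w = np.asarray(dwls_weights, dtype=float)

    rng = np.random.default_rng(12345)
    best = None
    for attempt in range(n_restarts + 1):
        theta = _start_values(spec)
        if attempt > 0:
            theta = _clip_theta(spec, theta + rng.uniform(-0.3, 0.3, theta.size))
        theta, f_min, converged, J = _gauss_newton(
            spec, theta, r_obs, w, iu, tol=tol, max_iter=max_iter
        )
        if best is None or (converged and not best[2]) or (
            converged == best[2] and f_min < best[1]
        ):
            best = (theta, f_min, converged, J, attempt)
        if best[2]:
            break
    theta, f_min, converged, J, attempts = best

    sv = np.linalg.svd(np.sqrt(w)[:, None] * J, compute_uv=False)
    sv_ratio = float(sv.min() / max(sv.max(), 1e-300))
    identified = bool(sv_ratio > 1e-7)
    heywood = bool(np.any(np.abs(theta) >= _LOADING_BOUND - 1e-12))

    sigma, _ = _sigma_jac(spec, theta, iu)
    resid = r_obs - sigma
    chi2 = float((n - 1) * f_min)
    df = spec.df
    chi2_b = float((n - 1) * np.sum(w * r_obs**2))
    df_b = p * (p - 1) // 2
    cfi, rmsea = _cfi_rmsea(chi2, df, chi2_b, df_b, n)
    srmr = float(np.sqrt(np.mean(resid**2)))
    return CfaFit(
        spec=spec,
        theta=theta,
        f_min=f_min,
        chi_square=chi2,
        df=df,
        n_par=spec.n_par,
        cfi=cfi,
        rmsea=rmsea,
        srmr=srmr,
        n=n,
        converged=converged,
        identified=identified,
        heywood=heywood,
        n_restarts_used=attempts,
        min_singular_ratio=sv_ratio,
        residuals=resid if keep_residuals else None,
    )


def _gauss_newton(spec, theta, r_obs, w, iu, *, tol, max_iter):
    sigma, J = _sigma_jac(spec, theta, iu)
    resid = r_obs - sigma
    f = float(np.sum(w * resid**2))
    mu = 1e-6
    converged = False
    for _ in range(max_iter):
        g = J.T @ (w * resid)
        H = (J * w[:, None]).T @ J
        improved = False
        for _ in range(25):
            try:
                step = np.linalg.solve(H + mu * np.eye(H.shape[0]), g)
            except np.linalg.LinAlgError:
                mu *= 10.0
                continue
            trial = _clip_theta(spec, theta + step)
            sigma_t, J_t = _sigma_jac(spec, trial, iu)
            resid_t = r_obs - sigma_t
            f_t = float(np.sum(w * resid_t**2))
            if f_t <= f + 1e-15:
                improved = True
                break
            mu *= 10.0
        if not improved:
            break
        delta = f - f_t
        theta, sigma, J, resid, f = trial, sigma_t, J_t, resid_t, f_t
        mu = max(mu * 0.2, 1e-10)
        if delta < tol * (1.0 + f) and np.max(np.abs(step)) < 1e-7:
            converged = True
            break
    return theta, f, converged, J


def _cfi_rmsea(chi2, df, chi2_b, df_b, n):
    num = max(chi2 - df, 0.0)
    den = max(chi2_b - df_b, chi2 - df, 0.0)
    cfi = 1.0 if den == 0.0 else 1.0 - num / den
    cfi = float(np.clip(cfi, 0.0, 1.0))
    if df <= 0:
        raise ValueError("RMSEA undefined for a saturated model (df = 0)")
    rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))
    return cfi, rmsea


def fit_indices(fit: CfaFit, baseline: CfaFit) -> tuple[float, float, float]:
    """(CFI, RMSEA, SRMR) of ``fit`` relative to an independence baseline.

    ``baseline`` must be the zero-correlation model fitted on the same
    matrix and sample size (its chi-square is (n-1) * sum r^2).
    """
    if baseline.n != fit.n:
        raise ValueError("fit and baseline must share the sample size")
    cfi, rmsea = _cfi_rmsea(
        fit.chi_square, fit.df, baseline.chi_square, baseline.df, fit.n
    )
    return cfi, rmsea, fit.srmr


def independence_baseline(matrix, n: int) -> CfaFit:
    """Fit of the independence model (all off-diagonal correlations zero)."""
    R = matrix.rho if isinstance(matrix, PolychoricMatrix) else np.asarray(matrix)
    p = R.shape[0]
    iu = np.triu_indices(p, 1)
    r = R[iu]
    f_min = float(np.sum(r**2))
    df = p * (p - 1) // 2
    spec = CfaModelSpec(
        "baseline", "correlated", tuple(f"i{k}" for k in range(p)),
        np.zeros(p, np.intp), 1, description="independence baseline",
    )
    return CfaFit(
        spec=spec,
        theta=np.zeros(p),
        f_min=f_min,
        chi_square=float((n - 1) * f_min),
        df=df,
        n_par=p * _THRESHOLDS_PER_ITEM,
        cfi=1.0,
        rmsea=0.0,
        srmr=float(np.sqrt(np.mean(r**2))),
        n=n,
        converged=True,
        identified=True,
    )


def classify_fit(fit) -> str:
    """'good' / 'acceptable' / 'poor' per the conventional index cutoffs.

    good: CFI > .95, RMSEA < .05, SRMR < .08; acceptable: CFI > .90 with the
    same RMSEA/SRMR bounds; otherwise poor.  Accepts a CfaFit or a
    (cfi, rmsea, srmr) triple.
    """
    if isinstance(fit, CfaFit):
        cfi, rmsea, srmr = fit.cfi, fit.rmsea, fit.srmr
    else:
        cfi, rmsea, srmr = fit
    if cfi > 0.95 and rmsea < 0.05 and srmr < 0.08:
        return "good"
    if cfi > 0.90 and rmsea < 0.05 and srmr < 0.08:
        return "acceptable"
    return "poor"


# ---------------------------------------------------------------------------
# batched fitter for the constrained short-form model
# ---------------------------------------------------------------------------


def fit_shortform_batch(
    R_full: np.ndarray,
    subsets: np.ndarray,
    domain_of: np.ndarray,
    n: int,
    *,
    tol: float = 1e-11,
    max_iter: int = 80,
) -> dict[str, np.ndarray]:
    """Fit the equal-higher-order-loading hierarchical model to many subsets.

    ``subsets`` is an integer array (B, k) of column indices into ``R_full``;
    within every row the items must be grouped by domain (all candidate
    generators in this package emit them that way), so one same-domain mask
    serves the whole batch.  Gauss-Newton iterations run for all B problems
    simultaneously via batched normal equations; this is what makes the
    exhaustive tiny-pool oracle and the 1,000-draw random baseline feasible
    on one CPU.

    Returns per-subset arrays: lambda (B, k), gamma (B,), f_min, chi2, cfi,
    rmsea, srmr, converged.
    """
    subsets = np.asarray(subsets)
    if subsets.ndim == 1:
        subsets = subsets[None, :]
    B, k = subsets.shape
    dom = domain_of[subsets[0]]
    if not all(np.array_equal(domain_of[subsets[b]], dom) for b in range(min(B, 8))):
        # spot check only; full verification would defeat the batching
        raise ValueError("all subsets must share the same domain layout")
    same = dom[:, None] == dom[None, :]
    iu = np.triu_indices(k, 1)
    same_pair = same[iu]  # (P,)
    cross_pair = ~same_pair
    P = iu[0].size
    rows = np.arange(P)

    Rsub = R_full[subsets[:, :, None], subsets[:, None, :]]  # (B, k, k)
    r_obs = Rsub[:, iu[0], iu[1]]  # (B, P)

    lam = np.full((B, k), 0.5)
    gam = np.full(B, 0.5)

    def implied(lam, gam):
        w = np.where(same_pair[None, :], 1.0, (gam**2)[:, None])
        return lam[:, iu[0]] * lam[:, iu[1]] * w, w

    sigma, w_pair = implied(lam, gam)
    f = np.sum((r_obs - sigma) ** 2, axis=1)
    converged = np.zeros(B, dtype=bool)
    idx = np.arange(B)  # indices of still-active problems

    eye = np.eye(k + 1) * 1e-9
    for _ in range(max_iter):
        if idx.size == 0:
            break
        lam_a, gam_a, r_a, f_a = lam[idx], gam[idx], r_obs[idx], f[idx]
        w_a = np.where(same_pair[None, :], 1.0, (gam_a**2)[:, None])
        # Jacobian of sigma wrt (lam, gamma); each pair row touches exactly
        # two distinct item columns, so direct assignment suffices
        J = np.zeros((idx.size, P, k + 1))
        J[:, rows, iu[0]] = lam_a[:, iu[1]] * w_a
        J[:, rows, iu[1]] = lam_a[:, iu[0]] * w_a
        ll = lam_a[:, iu[0]] * lam_a[:, iu[1]]
        J[:, cross_pair, k] = 2.0 * gam_a[:, None] * ll[:, cross_pair]

        sigma_a = ll * w_a
        resid = r_a - sigma_a
        Jt = J.transpose(0, 2, 1)
        g = np.matmul(Jt, resid[..., None])[..., 0]
        H = np.matmul(Jt, J) + eye
        step = np.linalg.solve(H, g[..., None])[..., 0]

        lam_t = np.clip(lam_a + step[:, :k], -_LOADING_BOUND, _LOADING_BOUND)
        gam_t = np.clip(gam_a + step[:, k], -_LOADING_BOUND, _LOADING_BOUND)

        def f_of(lam_c, gam_c, r_c):
            w_c = np.where(same_pair[None, :], 1.0, (gam_c**2)[:, None])
            s_c = lam_c[:, iu[0]] * lam_c[:, iu[1]] * w_c
            return np.sum((r_c - s_c) ** 2, axis=1)

        f_t = f_of(lam_t, gam_t, r_a)
        # damped fallback for the (rare) elements where full GN overshot
        worse = f_t > f_a + 1e-14
        shrink = 1.0
        for _ in range(12):
            if not worse.any():
                break
            shrink *= 0.5
            lam_t[worse] = np.clip(
                lam_a[worse] + shrink * step[worse, :k],
                -_LOADING_BOUND, _LOADING_BOUND,
            )
            gam_t[worse] = np.clip(
                gam_a[worse] + shrink * step[worse, k],
                -_LOADING_BOUND, _LOADING_BOUND,
            )
            f_t[worse] = f_of(lam_t[worse], gam_t[worse], r_a[worse])
            worse = worse & (f_t > f_a + 1e-14)

        stepmax = np.max(np.abs(step), axis=1)
        newly = (f_a - f_t < tol * (1.0 + f_t)) & (stepmax < 1e-7) & ~worse
        ok = ~worse
        lam[idx[ok]], gam[idx[ok]], f[idx[ok]] = lam_t[ok], gam_t[ok], f_t[ok]
        converged[idx[newly]] = True
        idx = idx[~newly & ok]

    sigma, _ = implied(lam, gam)
    resid = r_obs - sigma
    chi2 = (n - 1) * f
    df = k * (k - 1) // 2 - (k + 1)
    chi2_b = (n - 1) * np.sum(r_obs**2, axis=1)
    df_b = P
    num = np.maximum(chi2 - df, 0.0)
    den = np.maximum(np.maximum(chi2_b - df_b, chi2 - df), 1e-300)
    cfi = np.clip(1.0 - num / den, 0.0, 1.0)
    rmsea = np.sqrt(np.maximum(chi2 - df, 0.0) / (df * (n - 1)))
    srmr = np.sqrt(np.mean(resid**2, axis=1))
    return {
        "lam": lam,
        "gamma": gam,
        "f_min": f,
        "chi2": chi2,
        "df": df,
        "cfi": cfi,
        "rmsea": rmsea,
        "srmr": srmr,
        "converged": converged,
    }
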