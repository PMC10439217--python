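"""Stage 2: confirmatory factor models fit to (S, V) by DWLS.

A :class:`ModelSpec` declares the loading pattern Lambda, factor covariance
pattern Psi (factor variances fixed to 1, so free entries are correlations)
and diagonal residuals Theta of the implied covariance

    Sigma(theta) = Lambda Psi Lambda' + Theta.

Estimation minimizes the diagonally weighted least squares discrepancy

    F(theta) = (s - sigma(theta))' W (s - sigma(theta)),   W = diag(V)^{-1}

with s = vech(S). Standard errors are the sandwich
(D'WD)^{-1} D'W V W D (D'WD)^{-1} with D the Jacobian of sigma at the
optimum, and the model chi-square is the mean-scaled residual statistic

    chi2 = df * (e'We) / tr(W A V A'),   A = I - D (D'WD)^{-1} D'W,

whose scaling makes its expectation df under the model, so it is referred to
a chi-square distribution with df degrees of freedom. AIC = chi2 + 2q; CFI
compares against an independence model (free variances, all covariances 0)
fit with the same machinery; SRMR is the root mean square residual after
standardizing observed and implied matrices to the correlation metric by the
observed variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import optimize
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

from gsemkit.covariance import GeneticCovariance
from gsemkit.vech import vech, vech_indices

FREE = "free"


def _is_free(v: Any) -> bool:
    return isinstance(v, str) and v == FREE


@dataclass
class ModelSpec:
    """Declarative latent factor model.

    loadings maps (item, factor) to ``"free"`` or a fixed float; pairs not
    present are fixed at 0. factor_cov maps (factor, factor) pairs likewise;
    the diagonal defaults to fixed 1 (standardized factors) and undeclared
    off-diagonals to fixed 0. residuals maps item to ``"free"`` (default) or
    a fixed value.
    """

    name: str
    items: list[str]
    factors: list[str]
    loadings: dict[tuple[str, str], Any]
    factor_cov: dict[tuple[str, str], Any] = field(default_factory=dict)
    residuals: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for it in self.items:
            self.residuals.setdefault(it, FREE)
        for (it, fa) in self.loadings:
            if it not in self.items:
                raise ValueError(f"loading on unknown item {it!r}")
            if fa not in self.factors:
                raise ValueError(f"loading on unknown factor {fa!r}")
        norm_cov: dict[tuple[str, str], Any] = {}
        for (f1, f2), v in self.factor_cov.items():
            if f1 not in self.factors or f2 not in self.factors:
                raise ValueError(f"factor covariance on unknown pair {(f1, f2)!r}")
            i1, i2 = self.factors.index(f1), self.factors.index(f2)
            key = (f1, f2) if i1 >= i2 else (f2, f1)
            if f1 == f2 and _is_free(v):
                raise ValueError("factor variances must be fixed (identification)")
            norm_cov[key] = v
        self.factor_cov = norm_cov
        if self.factors:
            loaded = {it for (it, _f) in self.loadings}
            missing = [it for it in self.items if it not in loaded]
            if missing:
                raise ValueError(f"items load on no factor: {missing}")

    def psi_value(self, f1: str, f2: str) -> Any:
        if f1 == f2:
            return self.factor_cov.get((f1, f1), 1.0)
        i1, i2 = self.factors.index(f1), self.factors.index(f2)
        key = (f1, f2) if i1 >= i2 else (f2, f1)
        return self.factor_cov.get(key, 0.0)


def free_parameter_names(spec: ModelSpec) -> list[tuple]:
    """Ordered free parameters: loadings, then factor covariances, then residuals."""
    names: list[tuple] = []
    for (it, fa), v in spec.loadings.items():
        if _is_free(v):
            names.append(("lambda", it, fa))
    for (f1, f2), v in spec.factor_cov.items():
        if _is_free(v):
            names.append(("psi", f1, f2))
    for it in spec.items:
        if _is_free(spec.residuals[it]):
            names.append(("theta", it))
    return names


def count_free_parameters(spec: ModelSpec) -> int:
    """q = free loadings + free factor covariances + free residuals."""
    return len(free_parameter_names(spec))


def model_df(spec: ModelSpec, m: int | None = None) -> int:
    """df = m(m+1)/2 - q; negative df means the model is under-identified."""
    if m is None:
        m = len(spec.items)
    df = m * (m + 1) // 2 - count_free_parameters(spec)
    if df < 0:
        raise ValueError(f"model {spec.name!r} is under-identified (df = {df})")
    return df


def _build_matrices(spec: ModelSpec, theta: np.ndarray):
    """Materialize (Lambda, Psi, Theta) from the pattern and free values."""
    m, f = len(spec.items), len(spec.factors)
    item_ix = {it: i for i, it in enumerate(spec.items)}
    fac_ix = {fa: i for i, fa in enumerate(spec.factors)}
    Lam = np.zeros((m, f))
    Psi = np.zeros((f, f))
    Th = np.zeros(m)
    names = free_parameter_names(spec)
    vals = dict(zip(names, np.asarray(theta, dtype=float)))
    for (it, fa), v in spec.loadings.items():
        Lam[item_ix[it], fac_ix[fa]] = vals[("lambda", it, fa)] if _is_free(v) else v
    for fa in spec.factors:
        Psi[fac_ix[fa], fac_ix[fa]] = spec.psi_value(fa, fa)
    for (f1, f2), v in spec.factor_cov.items():
        if f1 != f2:
            val = vals[("psi", f1, f2)] if _is_free(v) else v
            Psi[fac_ix[f1], fac_ix[f2]] = Psi[fac_ix[f2], fac_ix[f1]] = val
    for it in spec.items:
        v = spec.residuals[it]
        Th[item_ix[it]] = vals[("theta", it)] if _is_free(v) else v
    return Lam, Psi, Th


def implied_sigma(spec: ModelSpec, theta: np.ndarray) -> np.ndarray:
    """Sigma(theta) = Lambda Psi Lambda' + diag(Theta)."""
    Lam, Psi, Th = _build_matrices(spec, theta)
    if Lam.shape[1] == 0:
        return np.diag(Th)
    Sig = Lam @ Psi @ Lam.T + np.diag(Th)
    return (Sig + Sig.T) / 2


def _jacobian(spec: ModelSpec, theta: np.ndarray) -> np.ndarray:
    """Analytic d vech(Sigma) / d theta, one column per free parameter."""
    Lam, Psi, _Th = _build_matrices(spec, theta)
    m = len(spec.items)
    item_ix = {it: i for i, it in enumerate(spec.items)}
    fac_ix = {fa: i for i, fa in enumerate(spec.factors)}
    pairs = vech_indices(m)
    names = free_parameter_names(spec)
    J = np.zeros((len(pairs), len(names)))
    LP = Lam @ Psi if Lam.size else np.zeros((m, 0))
    for col, name in enumerate(names):
        dS = np.zeros((m, m))
        if name[0] == "lambda":
            _, it, fa = name
            i, f = item_ix[it], fac_ix[fa]
            dS[i, :] += LP[:, f]
            dS[:, i] += LP[:, f]
        elif name[0] == "psi":
            _, f1, f2 = name
            a, b = fac_ix[f1], fac_ix[f2]
            dS += np.outer(Lam[:, a], Lam[:, b])
            dS += np.outer(Lam[:, b], Lam[:, a])
        else:
            _, it = name
            dS[item_ix[it], item_ix[it]] = 1.0
        J[:, col] = [dS[i, j] for i, j in pairs]
    return J


def smooth_to_pd(S: np.ndarray, epsilon: float = 1e-8):
    """Nearest (Frobenius) symmetric matrix with eigenvalues >= epsilon.

    Eigenvalue clipping on the symmetric part; returns the smoothed matrix
    and the maximum element-wise change for logging.
    """
    S = np.asarray(S, dtype=float)
    Ssym = (S + S.T) / 2
    vals, vecs = np.linalg.eigh(Ssym)
    if vals.min() >= epsilon:
        return Ssym, 0.0
    clipped = np.clip(vals, epsilon, None)
    out = vecs @ np.diag(clipped) @ vecs.T
    out = (out + out.T) / 2
    return out, float(np.abs(out - Ssym).max())


@dataclass
class FitResult:
    """Estimates, corrected chi-square and fit indices of one DWLS fit."""

    model_name: str
    param_names: list[tuple]
    estimates: np.ndarray
    se: np.ndarray
    chisq: float
    df: int
    p_value: float
    q: int
    AIC: float
    F_min: float
    converged: bool
    n_iterations: int
    implied: np.ndarray
    CFI: float | None = None
    SRMR: float | None = None
    standardized_loadings: dict | None = None
    factor_correlations: dict | None = None
    warnings: list[str] = field(default_factory=list)

    def estimate(self, name: tuple) -> float:
        return float(self.estimates[self.param_names.index(name)])

    def se_of(self, name: tuple) -> float:
        return float(self.se[self.param_names.index(name)])

    def p_of(self, name: tuple) -> float:
        se = self.se_of(name)
        if se == 0:
            return np.nan
        return 2 * norm.sf(abs(self.estimate(name)) / se)

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "chisq": self.chisq,
            "df": self.df,
            "p_value": self.p_value,
            "AIC": self.AIC,
            "CFI": self.CFI,
            "SRMR": self.SRMR,
            "converged": self.converged,
            "parameters": [
                {"name": list(n), "estimate": float(e), "se": float(s)}
                for n, e, s in zip(self.param_names, self.estimates, self.se)
            ],
            "warnings": self.warnings,
        }


def _start_values(spec: ModelSpec, S: np.ndarray) -> np.ndarray:
    d = np.diag(S)
    item_ix = {it: i for i, it in enumerate(spec.items)}
    x0 = []
    for name in free_parameter_names(spec):
        if name[0] == "lambda":
            x0.append(0.5 * np.sqrt(max(d[item_ix[name[1]]], 1e-8)))
        elif name[0] == "psi":
            x0.append(0.0)
        else:
            x0.append(0.5 * max(d[item_ix[name[1]]], 1e-8))
    return np.array(x0)


def fit_dwls(
    spec: ModelSpec,
    gc: GeneticCovariance,
    compute_indices: bool = True,
    gtol: float = 1e-8,
    smooth_eps: float | None = None,
    x0: np.ndarray | None = None,
) -> FitResult:
    """Fit a latent factor model to (S, V) by diagonally weighted least squares.

    The empirical S is smoothed to positive definite (eigenvalue clipping) if
    needed before vech-ing. ``converged`` reports whether the max absolute
    gradient of F fell below ``gtol`` — it is never forced true.
    """
    sub = gc.subset(spec.items) if list(gc.trait_names) != list(spec.items) else gc
    if smooth_eps is None:
        smooth_eps = 1e-8 * max(float(np.diag(sub.S).max()), 1.0)
    S_pd, max_change = smooth_to_pd(sub.S, smooth_eps)
    s = vech(S_pd)
    d = np.diag(sub.V).copy()
    zero = np.where(d <= 0)[0]
    if zero.size:
        pairs = vech_indices(sub.m)
        bad = [(sub.trait_names[pairs[z][0]], sub.trait_names[pairs[z][1]]) for z in zero]
        raise ValueError(f"V has non-positive diagonal for moment(s) {bad}")
    w = 1.0 / d
    sw = np.sqrt(w)

    names = free_parameter_names(spec)
    q = len(names)
    df = model_df(spec)
    theta0 = _start_values(spec, S_pd) if x0 is None else np.asarray(x0, dtype=float)

    def resid(th):
        return sw * (vech(implied_sigma(spec, th)) - s)

    def jac(th):
        return sw[:, None] * _jacobian(spec, th)

    if q > 0:
        sol = optimize.least_squares(
            resid, theta0, jac=jac, method="lm", xtol=1e-13, ftol=1e-13,
            gtol=1e-13, max_nfev=150 * max(q, 1),
        )
        theta = sol.x
        n_iter = int(sol.nfev)
    else:
        theta = theta0
        n_iter = 0

    e = s - vech(implied_sigma(spec, theta))
    grad = -2.0 * (_jacobian(spec, theta).T @ (w * e)) if q else np.zeros(0)
    # gradient tolerance is relative to the weighted data norm: the weights
    # 1/diag(V) carry the (arbitrary) scale of V, so an absolute cutoff
    # would be meaningless across inputs
    grad_scale = max(1.0, float(s @ (w * s)))
    converged = bool(q == 0 or np.max(np.abs(grad)) < gtol * grad_scale)
    F_min = float(e @ (w * e))

    warns: list[str] = []
    if max_change > 0:
        warns.append(f"S smoothed to PD (max element change {max_change:.3g})")
    Lam, Psi, Th = _build_matrices(spec, theta)
    if (Th < 0).any():
        neg = [spec.items[i] for i in np.where(Th < 0)[0]]
        warns.append(f"Heywood case: negative residual variance for {neg}")

    # sandwich SEs and mean-scaled residual chi-square using the full V
    if q > 0:
        D = _jacobian(spec, theta)
        B = D.T @ (w[:, None] * D)
        Binv = np.linalg.pinv(B)
        WD = w[:, None] * D
        cov = Binv @ (WD.T @ sub.V @ WD) @ Binv
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        A = np.eye(len(s)) - D @ Binv @ WD.T
        trace = float(np.trace((w[:, None] * (A @ sub.V @ A.T))))
    else:
        se = np.zeros(0)
        trace = float(np.sum(w * np.diag(sub.V)))
    if df > 0 and trace > 0:
        chisq = df * F_min / trace
        p_value = float(chi2_dist.sf(chisq, df))
    else:
        chisq, p_value = 0.0, 1.0

    fit = FitResult(
        model_name=spec.name,
        param_names=names,
        estimates=np.asarray(theta, dtype=float),
        se=se,
        chisq=float(chisq),
        df=df,
        p_value=p_value,
        q=q,
        AIC=float(chisq + 2 * q),
        F_min=F_min,
        converged=converged,
        n_iterations=n_iter,
        implied=implied_sigma(spec, theta),
        warnings=warns,
    )
    std_load, fac_corr = standardized_solution(fit, spec)
    fit.standardized_loadings = std_load
    fit.factor_correlations = fac_corr
    if compute_indices:
        indep = independence_spec(spec.items)
        fit_ind = fit_dwls(indep, sub, compute_indices=False, gtol=gtol)
        fit.AIC, fit.CFI, fit.SRMR = fit_indices(fit, sub, fit_ind)
    return fit


def independence_spec(items: list[str]) -> ModelSpec:
    """Baseline model: free variances only, every covariance fixed to 0."""
    return ModelSpec(
        name="independence", items=list(items), factors=[], loadings={}
    )


def fit_indices(
    fit: FitResult, gc: GeneticCovariance, fit_independence: FitResult
) -> tuple[float, float | None, float]:
    """(AIC, CFI, SRMR) for a fitted model.

    CFI = [(chi2_ind - df_ind) - (chi2_mod - df_mod)] / (chi2_ind - df_ind),
    clipped to [0, 1]; undefined (None, with a warning recorded on the fit)
    when the independence chi-square does not exceed its df. SRMR
    standardizes observed and implied matrices by the observed variances and
    averages squared residuals over all m(m+1)/2 unique elements.
    """
    aic = fit.chisq + 2 * fit.q
    denom = fit_independence.chisq - fit_independence.df
    if denom <= 0:
        fit.warnings.append("independence chi-square <= df: CFI undefined")
        cfi = None
    else:
        cfi = float(np.clip((denom - (fit.chisq - fit.df)) / denom, 0.0, 1.0))
    S = gc.S
    if S.shape != fit.implied.shape:
        raise ValueError("gc does not match the fitted model's items")
    sd = np.sqrt(np.diag(S))
    scale = np.outer(sd, sd)
    resid = (S - fit.implied) / scale
    srmr = float(np.sqrt(np.mean(vech(resid) ** 2)))
    return float(aic), cfi, srmr


def standardized_solution(fit: FitResult, spec: ModelSpec):
    """Loadings scaled to unit implied item variances, plus factor correlations.

    Sign convention: each factor is oriented so its largest-|loading| is
    positive. With factor variances fixed at 1 the factor covariances are
    correlations and are unchanged by the item standardization (apart from
    the orientation flips).
    """
    Lam, Psi, Th = _build_matrices(spec, fit.estimates)
    m, f = Lam.shape
    var = np.diag(fit.implied).copy()
    heywood = var <= 0
    if heywood.any():
        fit.warnings.append(
            f"non-positive implied variance for {[spec.items[i] for i in np.where(heywood)[0]]}"
        )
    sd = np.sqrt(np.abs(var))
    sd[sd == 0] = 1.0
    Lstd = Lam / sd[:, None]
    flips = np.ones(f)
    for k in range(f):
        col = Lstd[:, k]
        if col.size and col[np.argmax(np.abs(col))] < 0:
            flips[k] = -1.0
    Lstd = Lstd * flips[None, :]
    Psi_flip = Psi * np.outer(flips, flips)
    dpsi = np.sqrt(np.diag(Psi_flip)) if f else np.array([])
    corr = Psi_flip / np.outer(dpsi, dpsi) if f else Psi_flip
    std_load = {
        (it, fa): float(Lstd[i, k])
        for (it, fa) in spec.loadings
        for i, k in [(spec.items.index(it), spec.factors.index(fa))]
    }
    fac_corr = {
        (f1, f2): float(corr[spec.factors.index(f1), spec.factors.index(f2)])
        for f1 in spec.factors
        for f2 in spec.factors
        if spec.factors.index(f1) > spec.factors.index(f2)
    }
    return std_load, fac_corr
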