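"""Stage 1: multivariable LD score regression.

For traits i, k and SNP j the regression model is

    E[z_ij * z_kj] = sqrt(N_i N_k) * sigma_g(i,k) * l_j / M + intercept(i,k)

where l_j is the LD score, M the SNP count underlying its normalization,
sigma_g the genetic covariance (heritability when i = k), and the free
intercept absorbs confounding and, off-diagonal, sample overlap. Each pair is
fit by two-pass weighted least squares (first pass unweighted; second pass
with weights combining LD over-counting and the heteroskedasticity of
z-score products). The sampling covariance V of all unique elements of S is
a delete-one block jackknife over a shared contiguous SNP partition, so
cross-element dependencies are captured.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from gsemkit.covariance import GeneticCovariance
from gsemkit.sumstats import LDScoreReference, SumStatsTable
from gsemkit.vech import vech_index_of, vech_indices


@dataclass
class JackknifeConfig:
    """Delete-one block jackknife settings: contiguous blocks in genome order."""

    n_blocks: int = 200

    def validate(self, n_snps: int) -> None:
        if not (2 <= self.n_blocks <= n_snps):
            raise ValueError(
                f"n_blocks={self.n_blocks} must be in [2, {n_snps}] (number of SNPs)"
            )


class DegenerateRegressorError(ValueError):
    pass


def _intersect(tables: list[SumStatsTable], ref: LDScoreReference):
    """Common SNP set across all tables and the reference, genome-ordered."""
    common = set(ref.records["snp"])
    for t in tables:
        common &= set(t.records["snp"])
    if len(common) < 200:
        raise ValueError(f"only {len(common)} SNPs common to all inputs (< 200)")
    refdf = ref.records[ref.records["snp"].isin(common)].copy()
    refdf["__chr"] = refdf["chrom"].astype(str)
    refdf = refdf.sort_values(["__chr", "pos"], kind="mergesort").reset_index(drop=True)
    order = refdf["snp"]
    n, m = len(order), len(tables)
    Z = np.empty((n, m))
    N = np.empty((n, m))
    for k, t in enumerate(tables):
        sub = t.records.set_index("snp").loc[order]
        Z[:, k] = sub["z"].to_numpy()
        N[:, k] = sub["n"].to_numpy()
    ell = refdf["ld_score"].to_numpy(dtype=float)
    return Z, N, ell


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted least squares of y on [1, x]; returns (intercept, slope)."""
    X = np.column_stack([np.ones_like(x), x])
    A = X.T @ (w[:, None] * X)
    if abs(np.linalg.det(A)) < 1e-30 * max(A[0, 0], 1.0) ** 2 or np.ptp(x) == 0:
        raise DegenerateRegressorError(
            "LD score regressor is (numerically) constant: slope not identifiable"
        )
    c = X.T @ (w * y)
    sol = np.linalg.solve(A, c)
    return float(sol[0]), float(sol[1])


def _block_bounds(n: int, n_blocks: int) -> np.ndarray:
    """Start indices (length n_blocks + 1) of contiguous equal-size blocks."""
    return np.linspace(0, n, n_blocks + 1).astype(int)


def _jackknife_fit(x, y, w, bounds):
    """Weighted fit plus delete-one-block estimates of (intercept, slope).

    Returns full-data (intercept, slope) and the (n_blocks, 2) matrix of
    leave-one-block-out estimates, computed from per-block normal-equation
    sums so the whole jackknife is O(n).
    """
    X = np.column_stack([np.ones_like(x), x])
    wX = w[:, None] * X
    n_blocks = len(bounds) - 1
    A_blocks = np.empty((n_blocks, 2, 2))
    c_blocks = np.empty((n_blocks, 2))
    for b in range(n_blocks):
        s = slice(bounds[b], bounds[b + 1])
        A_blocks[b] = X[s].T @ wX[s]
        c_blocks[b] = X[s].T @ (w[s] * y[s])
    A = A_blocks.sum(axis=0)
    c = c_blocks.sum(axis=0)
    if abs(np.linalg.det(A)) < 1e-30 * max(A[0, 0], 1.0) ** 2 or np.ptp(x) == 0:
        raise DegenerateRegressorError(
            "LD score regressor is (numerically) constant: slope not identifiable"
        )
    full = np.linalg.solve(A, c)
    loo = np.empty((n_blocks, 2))
    for b in range(n_blocks):
        loo[b] = np.linalg.solve(A - A_blocks[b], c - c_blocks[b])
    return full, loo


def _pair_weights(ell, mu_i, mu_k, mu_ik):
    """Second-pass weights: 1 / [max(l,1) * (mu_i*mu_k + mu_ik^2)].

    mu are first-pass fitted means of z_i^2, z_k^2 and z_i*z_k; the product
    term is the large-sample variance of a bivariate-normal product, the
    max(l,1) term down-weights SNPs whose signal is over-counted by LD.
    """
    var = np.clip(mu_i * mu_k + mu_ik**2, 0.05, None)
    return 1.0 / (np.clip(ell, 1.0, None) * var)


def _fit_all_pairs(Z, N, ell, M, jk: JackknifeConfig):
    """Fit every pair (i >= k) with shared blocks; return slopes in sigma units.

    Returns (sigma vech, intercept matrix, loo sigma estimates of shape
    (n_blocks, p), loo intercept estimates of the same shape).
    """
    n, m = Z.shape
    jk.validate(n)
    bounds = _block_bounds(n, jk.n_blocks)
    pairs = vech_indices(m)
    p = len(pairs)

    # first pass: unweighted univariate fits give the mean functions
    mu = np.empty((n, m))
    for i in range(m):
        x = N[:, i] * ell / M
        a0, b0 = _wls(x, Z[:, i] ** 2, np.ones(n))
        mu[:, i] = np.clip(a0 + b0 * x, 0.05, None)

    sigma = np.empty(p)
    inter = np.empty((m, m))
    loo_sigma = np.empty((jk.n_blocks, p))
    loo_inter = np.empty((jk.n_blocks, p))
    for idx, (i, k) in enumerate(pairs):
        x = np.sqrt(N[:, i] * N[:, k]) * ell / M
        y = Z[:, i] * Z[:, k]
        if i == k:
            mu_ik = mu[:, i]
        else:
            a0, b0 = _wls(x, y, np.ones(n))
            mu_ik = a0 + b0 * x
        w = _pair_weights(ell, mu[:, i], mu[:, k], mu_ik)
        full, loo = _jackknife_fit(x, y, w, bounds)
        # slope of y on x = sqrt(NiNk) l / M is sigma_g directly
        sigma[idx] = full[1]
        inter[i, k] = inter[k, i] = full[0]
        loo_sigma[:, idx] = loo[:, 1]
        loo_inter[:, idx] = loo[:, 0]
    return sigma, inter, loo_sigma, loo_inter


def _jackknife_cov(est: np.ndarray, loo: np.ndarray) -> np.ndarray:
    """Block-jackknife covariance from full-data and leave-one-out estimates."""
    n_blocks = loo.shape[0]
    pseudo = n_blocks * est[None, :] - (n_blocks - 1) * loo
    return np.atleast_2d(np.cov(pseudo, rowvar=False)) / n_blocks


@dataclass
class PairFit:
    """One LDSC regression: estimate, intercept, jackknife SEs, per-block fits."""

    sigma: float
    intercept: float
    se: float
    intercept_se: float
    loo_sigma: np.ndarray


def univariate_h2(
    ss: SumStatsTable, ref: LDScoreReference, jk: JackknifeConfig = JackknifeConfig()
) -> PairFit:
    """SNP heritability of one trait by LD score regression.

    ``sigma`` is the observed-scale h2; SEs are block-jackknife SEs.
    """
    Z, N, ell = _intersect([ss], ref)
    sigma, inter, loo, loo_int = _fit_all_pairs(Z, N, ell, ref.M, jk)
    se = float(np.sqrt(_jackknife_cov(sigma, loo)[0, 0]))
    int_se = float(np.sqrt(_jackknife_cov(np.array([inter[0, 0]]), loo_int)[0, 0]))
    return PairFit(float(sigma[0]), float(inter[0, 0]), se, int_se, loo[:, 0])


def bivariate_gcov(
    ss1: SumStatsTable,
    ss2: SumStatsTable,
    ref: LDScoreReference,
    jk: JackknifeConfig = JackknifeConfig(),
) -> PairFit:
    """Genetic covariance of two traits from the z-score product regression.

    Blocks are the same contiguous partition the univariate fits use, so the
    jackknife SE is consistent with the multivariable V's diagonal.
    """
    Z, N, ell = _intersect([ss1, ss2], ref)
    sigma, inter, loo, loo_int = _fit_all_pairs(Z, N, ell, ref.M, jk)
    idx = vech_index_of(1, 0)
    cov = _jackknife_cov(sigma, loo)
    int_cov = _jackknife_cov(np.array([inter[i, j] for i, j in vech_indices(2)]), loo_int)
    return PairFit(
        float(sigma[idx]),
        float(inter[1, 0]),
        float(np.sqrt(cov[idx, idx])),
        float(np.sqrt(int_cov[idx, idx])),
        loo[:, idx],
    )


def multivariable_ldsc(
    tables: list[SumStatsTable],
    ref: LDScoreReference,
    jk: JackknifeConfig = JackknifeConfig(),
) -> GeneticCovariance:
    """Estimate S, V and the intercept matrix for two or more traits.

    All pairwise regressions run on the common SNP intersection with a shared
    block partition; V is the jackknife covariance of the full vech(S)
    pseudovalue vectors, so it carries the cross-element dependencies the
    stage-2 corrections need.
    """
    if len(tables) < 2:
        raise ValueError("multivariable_ldsc needs at least 2 traits")
    names = [t.trait_name for t in tables]
    Z, N, ell = _intersect(tables, ref)
    try:
        sigma, inter, loo, _loo_int = _fit_all_pairs(Z, N, ell, ref.M, jk)
    except DegenerateRegressorError:
        raise
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"pairwise LDSC fit failed for traits {names}: {exc}")
    V = _jackknife_cov(sigma, loo)
    m = len(tables)
    S = np.empty((m, m))
    for idx, (i, k) in enumerate(vech_indices(m)):
        S[i, k] = S[k, i] = sigma[idx]
    K = np.array([
        t.population_prevalence if t.population_prevalence is not None else np.nan
        for t in tables
    ])
    P = np.array([
        t.sample_prevalence if t.sample_prevalence is not None else np.nan
        for t in tables
    ])
    return GeneticCovariance(
        trait_names=names,
        S=S,
        V=V,
        intercepts=inter,
        scale=["observed"] * m,
        K=K,
        P=P,
    )


def liability_factor(K: float, P: float) -> float:
    """Observed-to-liability conversion factor for a case/control trait.

    c = K^2 (1-K)^2 / (phi(t)^2 * P (1-P)), with t the upper-K-tail standard
    normal threshold and phi the normal density. At K = P = 0.5 this is
    exactly pi/2.
    """
    if not (0 < K < 1):
        raise ValueError(f"population prevalence K={K} outside (0, 1)")
    if not (0 < P < 1):
        raise ValueError(f"sample prevalence P={P} outside (0, 1)")
    z = norm.pdf(norm.isf(K))
    return (K**2 * (1 - K) ** 2) / (z**2 * P * (1 - P))


def liability_convert(
    gc: GeneticCovariance, prevalences: dict[str, float] | None = None
) -> GeneticCovariance:
    """Convert binary traits' rows/columns of S (and V) to the liability scale.

    Each trait gets a factor c_i (1 for continuous traits); S[i, j] is
    multiplied by sqrt(c_i c_j) and V rows/columns of each vech element by
    the same pair factor. ``prevalences`` overrides/provides population
    prevalence K per trait name; sample prevalence P comes from the stored
    case/control metadata.
    """
    m = gc.m
    c = np.ones(m)
    scale = list(gc.scale)
    K_arr = gc.K.copy()
    for i, name in enumerate(gc.trait_names):
        K = (prevalences or {}).get(name, gc.K[i])
        if np.isnan(K):
            continue  # continuous trait
        P = gc.P[i]
        if np.isnan(P):
            raise ValueError(
                f"binary trait {name!r} has prevalence K but no case/control counts"
            )
        c[i] = liability_factor(float(K), float(P))
        scale[i] = "liability"
        K_arr[i] = K
    root = np.sqrt(c)
    S = gc.S * np.outer(root, root)
    pair_factor = np.array([root[i] * root[j] for i, j in vech_indices(m)])
    V = gc.V * np.outer(pair_factor, pair_factor)
    return GeneticCovariance(
        trait_names=list(gc.trait_names),
        S=S,
        V=V,
        intercepts=gc.intercepts.copy(),
        scale=scale,
        K=K_arr,
        P=gc.P.copy(),
    )


def genetic_correlation_matrix(gc: GeneticCovariance):
    """Genetic correlations r_g[i,j] = S[i,j]/sqrt(S[i,i] S[j,j]) with SEs.

    Standard errors come from the delta method applied to V; the diagonal is
    exactly 1 with SE 0.
    """
    d = np.diag(gc.S)
    bad = np.where(d <= 0)[0]
    if bad.size:
        raise ValueError(
            f"non-positive heritability for trait(s) {[gc.trait_names[i] for i in bad]}"
        )
    m = gc.m
    R = gc.S / np.sqrt(np.outer(d, d))
    np.fill_diagonal(R, 1.0)
    SE = np.zeros((m, m))
    for i in range(m):
        for j in range(i):
            idx = [vech_index_of(i, j), vech_index_of(i, i), vech_index_of(j, j)]
            r = R[i, j]
            g = np.array([
                1.0 / np.sqrt(d[i] * d[j]),
                -r / (2 * d[i]),
                -r / (2 * d[j]),
            ])
            var = float(g @ gc.V[np.ix_(idx, idx)] @ g)
            SE[i, j] = SE[j, i] = np.sqrt(max(var, 0.0))
    return R, SE
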