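"""Synthetic multi-trait GWAS summary statistics with known genetic truth.

Summary statistics are simulated at the z-score level: for SNP j the trait
vector z_j is drawn from a multivariate normal with covariance

    C_j = l_j * B + O,      B[i,k] = sqrt(N_i N_k) * Sigma_obs[i,k] / M

where Sigma_obs is the observed-scale genetic covariance (liability-scale
entries divided analytically by the liability factors for binary traits, so
the liability conversion recovers the configured truth exactly in
expectation) and O is the intercept matrix (diagonal 1; off-diagonal the
sample-overlap intercept, overlap fraction times a phenotypic-correlation
proxy). This is the exact generative inverse of the stage-1 regression
E[z_i z_k] = sqrt(N_i N_k) Sigma[i,k] l_j / M + O[i,k]: the module's core
contract, tested via slope recovery. SNPs are independent, which is also
what makes the block jackknife approximately valid here.

Drawing uses a single factorization, z_j = sqrt(l_j) * L_B u_j + L_O v_j
with L_B L_B' = B and L_O L_O' = O, so no per-SNP Cholesky is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gsemkit.covariance import GeneticCovariance
from gsemkit.ldsc import liability_factor
from gsemkit.sem import ModelSpec, implied_sigma
from gsemkit.sumstats import LDScoreReference, SumStatsTable
from gsemkit.vech import unvech, vech


@dataclass
class SimulationConfig:
    """Ground truth and cohort design for the z-score generator.

    Lambda/Psi/Theta are on the genetic-covariance scale (heritabilities on
    the implied diagonal). ``binary`` maps trait name to (K, P); those
    traits are emitted on the observed scale. ``overlap`` is the off-diagonal
    intercept matrix (zeros when cohorts do not overlap). ``seed`` is
    mandatory: every generator is a pure function of (config, seed).
    """

    trait_names: list[str]
    Lambda: np.ndarray
    Psi: np.ndarray
    Theta: np.ndarray  # diagonal vector
    M: int
    N: np.ndarray  # per-trait sample size
    seed: int
    binary: dict[str, tuple[float, float]] = field(default_factory=dict)
    overlap: np.ndarray | None = None
    ld_mean: float = 30.0
    ld_shape: float = 1.2
    qc_noise: bool = False

    def __post_init__(self) -> None:
        self.Lambda = np.atleast_2d(np.asarray(self.Lambda, dtype=float))
        self.Psi = np.atleast_2d(np.asarray(self.Psi, dtype=float))
        self.Theta = np.asarray(self.Theta, dtype=float)
        self.N = np.asarray(self.N, dtype=float)
        m = len(self.trait_names)
        if self.overlap is None:
            self.overlap = np.zeros((m, m))
        if self.seed is None:
            raise ValueError("seed is mandatory")
        sig = self.sigma_g()
        if np.linalg.eigvalsh(sig).min() <= 0:
            raise ValueError("implied genetic covariance is not positive definite")

    def sigma_g(self) -> np.ndarray:
        sig = self.Lambda @ self.Psi @ self.Lambda.T + np.diag(self.Theta)
        return (sig + sig.T) / 2

    def liability_factors(self) -> np.ndarray:
        c = np.ones(len(self.trait_names))
        for i, name in enumerate(self.trait_names):
            if name in self.binary:
                K, P = self.binary[name]
                c[i] = liability_factor(K, P)
        return c

    def sigma_observed(self) -> np.ndarray:
        """Observed-scale covariance: liability entries divided by sqrt(c_i c_k)."""
        root = np.sqrt(self.liability_factors())
        return self.sigma_g() / np.outer(root, root)

    def intercept_matrix(self) -> np.ndarray:
        O = np.asarray(self.overlap, dtype=float).copy()
        np.fill_diagonal(O, 1.0)
        return O


@dataclass
class TruthManifest:
    """Exact generative quantities implied by a SimulationConfig."""

    trait_names: list[str]
    sigma_g: np.ndarray
    sigma_observed: np.ndarray
    intercepts: np.ndarray
    liability_factors: np.ndarray
    Lambda: np.ndarray
    Psi: np.ndarray
    Theta: np.ndarray

    @classmethod
    def from_config(cls, config: SimulationConfig) -> "TruthManifest":
        return cls(
            trait_names=list(config.trait_names),
            sigma_g=config.sigma_g(),
            sigma_observed=config.sigma_observed(),
            intercepts=config.intercept_matrix(),
            liability_factors=config.liability_factors(),
            Lambda=config.Lambda.copy(),
            Psi=config.Psi.copy(),
            Theta=config.Theta.copy(),
        )

    def to_dict(self) -> dict:
        return {
            "trait_names": self.trait_names,
            "sigma_g": self.sigma_g.tolist(),
            "sigma_observed": self.sigma_observed.tolist(),
            "intercepts": self.intercepts.tolist(),
            "liability_factors": self.liability_factors.tolist(),
            "Lambda": self.Lambda.tolist(),
            "Psi": self.Psi.tolist(),
            "Theta": self.Theta.tolist(),
        }


def simulate_ld_scores(
    M: int, mean: float = 30.0, shape: float = 1.2, seed: int = 0
) -> LDScoreReference:
    """Right-skewed positive LD scores (gamma) over M ordered synthetic SNPs."""
    if M < 1000:
        raise ValueError("M must be >= 1000 for a usable reference")
    rng = np.random.default_rng(seed)
    ell = rng.gamma(shape, mean / shape, size=M)
    ell = np.maximum(ell, 1e-3)
    df = pd.DataFrame({
        "snp": [f"rs{j:08d}" for j in range(M)],
        "chrom": "1",
        "pos": np.arange(1, M + 1) * 1000,
        "a1": "A",
        "a2": "G",
        "ld_score": ell,
    })
    return LDScoreReference(records=df, M=float(M))


def simulate_zscores(
    config: SimulationConfig, ref: LDScoreReference
) -> list[SumStatsTable]:
    """Draw per-SNP z-score vectors under the LD score regression expectation."""
    m = len(config.trait_names)
    ell = ref.records["ld_score"].to_numpy(dtype=float)
    n_snp = len(ell)
    sigma_obs = config.sigma_observed()
    O = config.intercept_matrix()
    rootN = np.sqrt(config.N)
    B = np.outer(rootN, rootN) * sigma_obs / ref.M
    try:
        L_B = np.linalg.cholesky(B)
        L_O = np.linalg.cholesky(O)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"per-SNP covariance is not positive definite under this configuration: {exc}"
        )
    rng = np.random.default_rng(config.seed)
    U = rng.standard_normal((n_snp, m))
    Vn = rng.standard_normal((n_snp, m))
    Z = np.sqrt(ell)[:, None] * (U @ L_B.T) + Vn @ L_O.T

    if config.qc_noise:
        info = rng.uniform(0.80, 1.0, size=n_snp)
        freq = rng.uniform(0.001, 0.5, size=n_snp)
    else:
        info = np.ones(n_snp)
        freq = rng.uniform(0.05, 0.5, size=n_snp)

    tables = []
    base = ref.records[["snp", "chrom", "pos", "a1", "a2"]].reset_index(drop=True)
    for i, name in enumerate(config.trait_names):
        rec = base.copy()
        rec["z"] = Z[:, i]
        rec["n"] = config.N[i]
        rec["info"] = info
        rec["freq"] = freq
        meta: dict = {}
        if name in config.binary:
            K, P = config.binary[name]
            n_cases = int(round(P * config.N[i]))
            meta = {
                "is_binary": True,
                "n_cases": n_cases,
                "n_controls": int(config.N[i]) - n_cases,
                "population_prevalence": K,
            }
            meta["n_effective"] = 4.0 / (1.0 / meta["n_cases"] + 1.0 / meta["n_controls"])
        tables.append(
            SumStatsTable(trait_name=name, records=rec, **meta)
        )
    return tables


# --- the 11-trait study design ------------------------------------------------

STUDY_TRAITS = [
    "DPW", "AUDITC_UKB", "AUDITC_MVP",
    "MAXALC", "AUDITP_UKB", "AUD_MVP", "AD_PGC",
    "SAT_FAMILY", "SAT_FRIENDS", "SAT_WORK", "SAT_FINANCE",
]

# standardized bifactor truth: common alcohol factor + orthogonal unique use
# and unique AUD group factors (alcohol dependence on the common factor only)
# + a satisfaction factor correlated -0.17 / 0.22 / 0 with them.
_STD_LOADINGS = {
    # item: (COMMON, U_USE, U_AUD, LS)
    "DPW": (0.55, 0.50, 0.0, 0.0),
    "AUDITC_UKB": (0.65, 0.55, 0.0, 0.0),
    "AUDITC_MVP": (0.60, 0.50, 0.0, 0.0),
    "MAXALC": (0.60, 0.0, 0.45, 0.0),
    "AUDITP_UKB": (0.65, 0.0, 0.50, 0.0),
    "AUD_MVP": (0.70, 0.0, 0.50, 0.0),
    "AD_PGC": (0.65, 0.0, 0.0, 0.0),
    "SAT_FAMILY": (0.0, 0.0, 0.0, 0.88),
    "SAT_FRIENDS": (0.0, 0.0, 0.0, 0.70),
    "SAT_WORK": (0.0, 0.0, 0.0, 0.50),
    "SAT_FINANCE": (0.0, 0.0, 0.0, 0.65),
}

_STD_PSI = np.array([
    [1.0, 0.0, 0.0, -0.17],
    [0.0, 1.0, 0.0, 0.22],
    [0.0, 0.0, 1.0, 0.00],
    [-0.17, 0.22, 0.0, 1.0],
])

# SNP heritabilities (diagonal of the genetic covariance), chosen in the
# 0.04-0.13 range reported for these trait classes.
_H2 = {
    "DPW": 0.05, "AUDITC_UKB": 0.08, "AUDITC_MVP": 0.068,
    "MAXALC": 0.07, "AUDITP_UKB": 0.068, "AUD_MVP": 0.068, "AD_PGC": 0.09,
    "SAT_FAMILY": 0.04, "SAT_FRIENDS": 0.04, "SAT_WORK": 0.04, "SAT_FINANCE": 0.04,
}

# case/control traits: (population prevalence K, sample prevalence P)
_BINARY = {
    "AD_PGC": (0.159, 11569 / (11569 + 34999)),
    "AUD_MVP": (0.159, 55584 / (55584 + 218807)),
}

_AUDIT_T = "AUDITT_23ANDME"


def standardized_truth(
    include_audit_t: bool = False,
    audit_t_loadings: tuple[float, float, float] = (0.55, 0.50, 0.0),
):
    """(trait_names, Lambda_std, Psi, Theta_std) of the study's generative truth.

    ``audit_t_loadings`` are AUDIT-T's standardized loadings on the common,
    unique-use and unique-AUD factors. The default places its signal on the
    common and use factors only, the scenario in which a three-factor screen
    assigns it a near-zero unique-AUD loading.
    """
    names = list(STUDY_TRAITS)
    rows = {k: list(v) for k, v in _STD_LOADINGS.items()}
    if include_audit_t:
        names.insert(3, _AUDIT_T)  # after the use items, before the AUD block
        common, use, aud = audit_t_loadings
        rows[_AUDIT_T] = [common, use, aud, 0.0]
    Lam = np.array([rows[n] for n in names])
    Theta = 1.0 - np.einsum("if,fg,ig->i", Lam, _STD_PSI, Lam)
    return names, Lam, _STD_PSI.copy(), Theta


def study_config(
    seed: int,
    n_per_trait: float = 20_000,
    M: int = 20_000,
    include_audit_t: bool = False,
    audit_t_loadings: tuple[float, float, float] = (0.55, 0.50, 0.0),
    with_overlap: bool = True,
) -> SimulationConfig:
    """Desk-scale study design: 11 (or 12) traits, M SNPs, N per trait."""
    names, Lam_std, Psi, Theta_std = standardized_truth(
        include_audit_t, audit_t_loadings
    )
    h2 = np.array([_H2.get(n, 0.06) for n in names])
    root = np.sqrt(h2)
    Lam = root[:, None] * Lam_std
    Theta = h2 * Theta_std
    m = len(names)
    O = np.zeros((m, m))
    if with_overlap:
        ix = {n: i for i, n in enumerate(names)}
        sats = ["SAT_FAMILY", "SAT_FRIENDS", "SAT_WORK", "SAT_FINANCE"]
        for a in sats:  # UKB satisfaction items: full overlap
            for b in sats:
                if a != b:
                    O[ix[a], ix[b]] = 0.35
        O[ix["AUDITC_UKB"], ix["AUDITP_UKB"]] = O[ix["AUDITP_UKB"], ix["AUDITC_UKB"]] = 0.20
        for b in ("AUDITC_UKB", "AUDITP_UKB"):  # DPW partially includes UKB
            O[ix["DPW"], ix[b]] = O[ix[b], ix["DPW"]] = 0.10
    return SimulationConfig(
        trait_names=names,
        Lambda=Lam,
        Psi=Psi,
        Theta=Theta,
        M=M,
        N=np.full(m, float(n_per_trait)),
        seed=seed,
        binary={k: v for k, v in _BINARY.items() if k in names},
        overlap=O,
    )


def simulate_study_design(
    seed: int,
    n_per_trait: float = 20_000,
    M: int = 20_000,
    include_audit_t: bool = False,
    audit_t_loadings: tuple[float, float, float] = (0.55, 0.50, 0.0),
    with_overlap: bool = True,
) -> tuple[list[SumStatsTable], LDScoreReference, TruthManifest]:
    """Generate the full multi-cohort design plus its truth manifest."""
    config = study_config(
        seed, n_per_trait, M, include_audit_t, audit_t_loadings, with_overlap
    )
    ref = simulate_ld_scores(M, seed=seed + 1)
    tables = simulate_zscores(config, ref)
    return tables, ref, TruthManifest.from_config(config)


def make_sv_fixture(
    spec: ModelSpec,
    theta_truth: np.ndarray,
    noise_scale: float = 0.01,
    seed: int = 0,
    cross_corr: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-test fixture bypassing stage 1: S = Sigma(theta) + noise ~ N(0, V).

    V is PSD by construction: Wishart-style diagonal
    v_ab = noise_scale^2 (sigma_ii sigma_jj + sigma_ij^2) with a small
    common-factor cross-correlation, V = sqrt(v) C sqrt(v)',
    C = (1-a) I + (a/p) 1 1'. The noise is drawn from exactly this V, so
    downstream sandwich SEs are calibrated against it.
    """
    sigma = implied_sigma(spec, theta_truth)
    s = vech(sigma)
    m = sigma.shape[0]
    p = len(s)
    d = np.diag(sigma)
    pairs = [(i, j) for i in range(m) for j in range(i + 1)]
    base = np.array([d[i] * d[j] + sigma[i, j] ** 2 for i, j in pairs])
    # noise_scale = 0 still needs a valid (PSD, positive-diagonal) V for the
    # DWLS weights; the noise itself is then exactly zero
    v = max(noise_scale, 1e-6) ** 2 * base
    C = (1 - cross_corr) * np.eye(p) + (cross_corr / p) * np.ones((p, p))
    root_v = np.sqrt(v)
    V = np.outer(root_v, root_v) * C
    rng = np.random.default_rng(seed)
    noise = (noise_scale / max(noise_scale, 1e-6)) * (
        np.linalg.cholesky(V) @ rng.standard_normal(p)
    )
    S = unvech(s + noise)
    return S, V


def fixture_gc(spec: ModelSpec, theta_truth, noise_scale=0.01, seed=0) -> GeneticCovariance:
    """Wrap :func:`make_sv_fixture` output as a GeneticCovariance."""
    S, V = make_sv_fixture(spec, theta_truth, noise_scale, seed)
    return GeneticCovariance(trait_names=list(spec.items), S=S, V=V)
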