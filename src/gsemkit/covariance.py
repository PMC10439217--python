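"""Genetic covariance container and S/V matrix file IO.

``GeneticCovariance`` carries the m x m genetic covariance matrix S (SNP
heritabilities on the diagonal, genetic covariances off it), the sampling
covariance V of vech(S) estimated by block jackknife, the LDSC intercept
matrix, and per-trait scale metadata. The file format is tab-delimited text
with a single JSON header line, so round-trips are bit-identical and
human-inspectable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from gsemkit.vech import VECH_ORDER_TAG, vech_index_of, vech_indices


@dataclass
class GeneticCovariance:
    """Stage-1 output: S, V, intercepts and scale metadata for m traits.

    Attributes
    ----------
    trait_names : ordered trait labels (length m)
    S : (m, m) genetic covariance; liability scale for converted binary traits
    V : (p, p) sampling covariance of vech(S), p = m(m+1)/2,
        vech in row-major lower-triangle order
    intercepts : (m, m); diagonal = univariate LDSC intercepts, off-diagonal =
        cross-trait intercepts absorbing sample overlap
    scale : per-trait flag, "observed" or "liability"
    K : per-trait population prevalence (NaN for continuous traits)
    P : per-trait sample prevalence (NaN for continuous traits)
    """

    trait_names: list[str]
    S: np.ndarray
    V: np.ndarray
    intercepts: np.ndarray | None = None
    scale: list[str] = field(default_factory=list)
    K: np.ndarray | None = None
    P: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        m = len(self.trait_names)
        p = m * (m + 1) // 2
        if self.S.shape != (m, m):
            raise ValueError(f"S has shape {self.S.shape}, expected {(m, m)}")
        if self.V.shape != (p, p):
            raise ValueError(
                f"V has shape {self.V.shape}, expected {(p, p)} for m={m}"
            )
        if not self.scale:
            self.scale = ["observed"] * m
        if self.intercepts is None:
            self.intercepts = np.full((m, m), np.nan)
        if self.K is None:
            self.K = np.full(m, np.nan)
        if self.P is None:
            self.P = np.full(m, np.nan)

    @property
    def m(self) -> int:
        return len(self.trait_names)

    def h2(self) -> np.ndarray:
        """SNP heritability point estimates (diagonal of S)."""
        return np.diag(self.S).copy()

    def h2_se(self) -> np.ndarray:
        """Jackknife standard errors of the heritabilities."""
        idx = [vech_index_of(i, i) for i in range(self.m)]
        return np.sqrt(np.diag(self.V)[idx])

    def element_se(self, i: int, j: int) -> float:
        """Jackknife SE of S[i, j]."""
        return float(np.sqrt(self.V[vech_index_of(i, j), vech_index_of(i, j)]))

    def subset(self, traits: list[str]) -> "GeneticCovariance":
        """Restrict to (and reorder by) the given trait names.

        V is subset consistently: rows/columns of vech elements whose trait
        pair survives are selected and reordered to the new vech order.
        """
        missing = [t for t in traits if t not in self.trait_names]
        if missing:
            raise KeyError(f"traits not present: {missing}")
        pos = [self.trait_names.index(t) for t in traits]
        S = self.S[np.ix_(pos, pos)]
        k = len(pos)
        vidx = [vech_index_of(pos[i], pos[j]) for i, j in vech_indices(k)]
        V = self.V[np.ix_(vidx, vidx)]
        return GeneticCovariance(
            trait_names=list(traits),
            S=S,
            V=V,
            intercepts=self.intercepts[np.ix_(pos, pos)],
            scale=[self.scale[i] for i in pos],
            K=self.K[pos],
            P=self.P[pos],
        )


def write_matrices(S, V, metadata: dict, path) -> None:
    """Write S and V with a JSON header recording trait order and vech order.

    ``metadata`` must contain ``trait_names``; ``scale`` flags optional.
    """
    S = np.asarray(S, dtype=float)
    V = np.asarray(V, dtype=float)
    m = S.shape[0]
    p = m * (m + 1) // 2
    if S.shape != (m, m) or not np.allclose(S, S.T, atol=1e-12):
        raise ValueError("S must be a symmetric square matrix")
    if V.shape != (p, p):
        raise ValueError(f"V side length {V.shape[0]} does not match m={m} (expected {p})")
    header = {
        "format": "gsemkit-sv",
        "m": m,
        "trait_names": list(metadata["trait_names"]),
        "vech_order": VECH_ORDER_TAG,
        "scale": list(metadata.get("scale", ["observed"] * m)),
    }
    with open(path, "w") as fh:
        fh.write("#" + json.dumps(header) + "\n")
        for row in S:
            fh.write("\t".join(repr(float(x)) for x in row) + "\n")
        for row in V:
            fh.write("\t".join(repr(float(x)) for x in row) + "\n")


def read_matrices(path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Read an S/V file written by :func:`write_matrices`.

    Raises if the vech order tag is absent or unknown — reading V under the
    wrong half-vectorization order would silently corrupt every downstream
    weight and standard error.
    """
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError("missing JSON header line in S/V file")
        header = json.loads(first[1:])
        if header.get("vech_order") != VECH_ORDER_TAG:
            raise ValueError(
                f"S/V file lacks the required vech order tag {VECH_ORDER_TAG!r}"
            )
        m = int(header["m"])
        p = m * (m + 1) // 2
        rows = [line.split("\t") for line in fh.read().splitlines() if line]
    if len(rows) != m + p:
        raise ValueError(f"expected {m}+{p} rows, found {len(rows)}")
    S = np.array([[float(x) for x in r] for r in rows[:m]])
    V = np.array([[float(x) for x in r] for r in rows[m:]])
    if S.shape != (m, m) or V.shape != (p, p):
        raise ValueError(f"malformed S/V block: S {S.shape}, V {V.shape}")
    return S, V, header


def gc_to_file(gc: GeneticCovariance, path) -> None:
    write_matrices(
        gc.S, gc.V, {"trait_names": gc.trait_names, "scale": gc.scale}, path
    )


def gc_from_file(path) -> GeneticCovariance:
    S, V, header = read_matrices(path)
    return GeneticCovariance(
        trait_names=header["trait_names"], S=S, V=V, scale=header.get("scale", [])
    )
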