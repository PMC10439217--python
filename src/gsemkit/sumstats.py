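"""Reading, quality control and allele harmonization of GWAS summary statistics.

A summary-statistics table holds one row per SNP with identifier, alleles,
a signed standardized effect z (beta/SE and log(OR)/SE are converted on
load), per-SNP sample size, and optional imputation INFO and allele
frequency. QC mirrors the standard munging pipeline for LD score regression:
drop non-SNP variants, strand-ambiguous pairs (A/T, C/G), low INFO, low MAF,
and low-N SNPs, in that fixed order so removal counts are reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

VALID_ALLELES = {"A", "C", "G", "T"}
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

#: canonical column names understood by read_sumstats
STANDARD_COLUMNS = (
    "snp", "chrom", "pos", "a1", "a2", "z", "beta", "se", "or", "n", "info", "freq",
)


@dataclass
class SumStatsTable:
    """Per-SNP association statistics plus trait metadata for one cohort."""

    trait_name: str
    records: pd.DataFrame
    is_binary: bool = False
    n_cases: int | None = None
    n_controls: int | None = None
    n_effective: float | None = None
    population_prevalence: float | None = None
    parse_rejections: int = 0

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sample_prevalence(self) -> float | None:
        if self.n_cases is None or self.n_controls is None:
            return None
        return self.n_cases / (self.n_cases + self.n_controls)


@dataclass
class HarmonizationReport:
    """Partition of input rows into retained and per-filter removals."""

    n_input: int = 0
    n_removed_nonsnp: int = 0
    n_removed_ambiguous: int = 0
    n_removed_info: int = 0
    n_removed_maf: int = 0
    n_removed_minN: int = 0
    n_flipped: int = 0
    n_retained: int = 0

    def check(self) -> None:
        removed = (
            self.n_removed_nonsnp
            + self.n_removed_ambiguous
            + self.n_removed_info
            + self.n_removed_maf
            + self.n_removed_minN
        )
        assert self.n_input == self.n_retained + removed, "report does not conserve rows"


@dataclass
class LDScoreReference:
    """Per-SNP LD scores plus the SNP count M normalizing them."""

    records: pd.DataFrame  # columns: snp, chrom, pos, a1, a2, ld_score
    M: float

    def __post_init__(self) -> None:
        if self.M <= 0:
            raise ValueError("M must be positive")
        neg = self.records["ld_score"] < 0
        if neg.any():
            # negative LD score estimates are floored at zero
            self.records = self.records.copy()
            self.records.loc[neg, "ld_score"] = 0.0

    def __len__(self) -> int:
        return len(self.records)


class ColumnMapError(KeyError):
    """A mandatory summary-statistics column could not be resolved."""


def read_sumstats(path, column_map: dict, trait_meta: dict) -> SumStatsTable:
    """Load one cohort's summary statistics from delimited text.

    Parameters
    ----------
    column_map : maps canonical names (``snp``, ``a1``, ``a2``, and one of
        ``z`` / ``beta``+``se`` / ``or``+``se``; optionally ``n``, ``chrom``,
        ``pos``, ``info``, ``freq``) to the file's header names. Effect
        precedence when several are mapped: z, then beta/se, then OR/se.
    trait_meta : ``trait_name`` plus optional ``is_binary``, ``n_cases``,
        ``n_controls``, ``n_effective``, ``population_prevalence``, and ``n``
        (fixed per-trait sample size broadcast when no per-SNP N column).

    Rows whose effect or N fails numeric parsing are rejected (counted in
    ``parse_rejections``), never silently kept.
    """
    raw = pd.read_csv(path, sep=r"\s+", dtype=str, compression="infer")
    for col in ("snp", "a1", "a2"):
        name = column_map.get(col)
        if name is None or name not in raw.columns:
            raise ColumnMapError(f"mandatory column {col!r} not resolvable (mapped to {name!r})")

    def _num(col: str) -> pd.Series | None:
        name = column_map.get(col)
        if name is None or name not in raw.columns:
            return None
        return pd.to_numeric(raw[name], errors="coerce")

    out = pd.DataFrame({
        "snp": raw[column_map["snp"]].astype(str),
        "a1": raw[column_map["a1"]].astype(str).str.upper(),
        "a2": raw[column_map["a2"]].astype(str).str.upper(),
    })
    chrom = column_map.get("chrom")
    out["chrom"] = raw[chrom].astype(str) if chrom and chrom in raw.columns else "NA"
    pos = _num("pos")
    out["pos"] = pos if pos is not None else np.arange(len(raw))

    z = _num("z")
    if z is None:
        se = _num("se")
        beta = _num("beta")
        if beta is not None and se is not None:
            z = beta / se
        else:
            orr = _num("or")
            if orr is not None and se is not None:
                z = np.log(orr) / se
            else:
                raise ColumnMapError(
                    "no effect column resolvable: need 'z', or 'beta'+'se', or 'or'+'se'"
                )
    out["z"] = z

    n = _num("n")
    if n is None:
        fixed_n = trait_meta.get("n")
        if fixed_n is None and trait_meta.get("n_cases") is not None:
            fixed_n = trait_meta["n_cases"] + trait_meta["n_controls"]
        if fixed_n is None:
            raise ColumnMapError("no per-SNP 'n' column and no fixed N in trait_meta")
        n = pd.Series(float(fixed_n), index=out.index)
    out["n"] = n

    for opt in ("info", "freq"):
        val = _num(opt)
        if val is not None:
            out[opt] = val

    ok = np.isfinite(out["z"]) & np.isfinite(out["n"]) & (out["n"] > 0)
    rejected = int((~ok).sum())
    out = out[ok].reset_index(drop=True)

    return SumStatsTable(
        trait_name=trait_meta["trait_name"],
        records=out,
        is_binary=bool(trait_meta.get("is_binary", False)),
        n_cases=trait_meta.get("n_cases"),
        n_controls=trait_meta.get("n_controls"),
        n_effective=trait_meta.get("n_effective"),
        population_prevalence=trait_meta.get("population_prevalence"),
        parse_rejections=rejected,
    )


def default_min_n(n: pd.Series) -> float:
    """Minimum-N rule: 90th percentile of per-SNP N divided by 1.5.

    Scale-free and matches the de-facto munging convention; for fixed-N
    cohorts (constant column) it removes nothing.
    """
    return float(np.quantile(n, 0.9)) / 1.5


def qc_filter(
    ss: SumStatsTable,
    min_info: float = 0.90,
    min_maf: float = 0.01,
    min_n_rule=default_min_n,
) -> tuple[SumStatsTable, HarmonizationReport]:
    """Apply the standard QC filters in fixed order.

    Order: non-SNP alleles → strand-ambiguous → INFO < min_info →
    MAF < min_maf → N below the min-N rule. INFO/MAF filters are no-ops when
    the column is absent. Idempotent by construction.
    """
    df = ss.records
    rep = HarmonizationReport(n_input=len(df))

    is_snp = df["a1"].isin(VALID_ALLELES) & df["a2"].isin(VALID_ALLELES) & (df["a1"] != df["a2"])
    rep.n_removed_nonsnp = int((~is_snp).sum())
    df = df[is_snp]

    amb = [(a, b) in AMBIGUOUS_PAIRS for a, b in zip(df["a1"], df["a2"])]
    amb = np.array(amb, dtype=bool) if len(df) else np.zeros(0, dtype=bool)
    rep.n_removed_ambiguous = int(amb.sum())
    df = df[~amb]

    if "info" in df.columns and len(df):
        keep = ~(df["info"] < min_info)  # missing INFO passes
        rep.n_removed_info = int((~keep).sum())
        df = df[keep]

    if "freq" in df.columns and len(df):
        maf = np.minimum(df["freq"], 1 - df["freq"])
        keep = ~(maf < min_maf)
        rep.n_removed_maf = int((~keep).sum())
        df = df[keep]

    if min_n_rule is not None and len(df):
        thr = min_n_rule(df["n"])
        keep = df["n"] >= thr
        rep.n_removed_minN = int((~keep).sum())
        df = df[keep]

    # enforce unique SNP ids (duplicates counted as non-SNP removals)
    if len(df):
        dup = df["snp"].duplicated(keep="first")
        rep.n_removed_nonsnp += int(dup.sum())
        df = df[~dup]

    rep.n_retained = len(df)
    rep.check()
    if rep.n_retained == 0:
        warnings.warn(f"QC removed every record of trait {ss.trait_name!r}", stacklevel=2)
    return replace(ss, records=df.reset_index(drop=True)), rep


def align_alleles(ss: SumStatsTable, ref: LDScoreReference) -> SumStatsTable:
    """Harmonize effect alleles to an LD score reference.

    Intersects on SNP id; swapped orientation negates z; strand-flipped
    alleles are complemented before matching; anything still unmatched is
    dropped. Requires >= 200 overlapping SNPs for a meaningful regression.
    """
    merged = ss.records.merge(
        ref.records[["snp", "a1", "a2"]].rename(columns={"a1": "ref_a1", "a2": "ref_a2"}),
        on="snp",
        how="inner",
    )
    if len(merged) == 0:
        raise ValueError(f"no SNP overlap between {ss.trait_name!r} and the reference")

    a1, a2 = merged["a1"], merged["a2"]
    c1 = a1.map(COMPLEMENT)
    c2 = a2.map(COMPLEMENT)
    same = (a1 == merged["ref_a1"]) & (a2 == merged["ref_a2"])
    swapped = (a1 == merged["ref_a2"]) & (a2 == merged["ref_a1"])
    flip_same = ~same & ~swapped & (c1 == merged["ref_a1"]) & (c2 == merged["ref_a2"])
    flip_swapped = ~same & ~swapped & (c1 == merged["ref_a2"]) & (c2 == merged["ref_a1"])

    keep = same | swapped | flip_same | flip_swapped
    merged = merged[keep]
    if len(merged) < 200:
        raise ValueError(
            f"only {len(merged)} SNPs of {ss.trait_name!r} align to the reference (< 200)"
        )
    negate = (swapped | flip_swapped)[keep]
    out = merged.copy()
    out.loc[negate, "z"] = -out.loc[negate, "z"]
    out["a1"] = merged["ref_a1"]
    out["a2"] = merged["ref_a2"]
    out = out.drop(columns=["ref_a1", "ref_a2"]).reset_index(drop=True)
    return replace(ss, records=out)


def write_ldscores(ref: LDScoreReference, prefix) -> None:
    """Write the de-facto ``.l2.ldscore`` layout plus the M companion file."""
    df = ref.records.rename(
        columns={"chrom": "CHR", "snp": "SNP", "pos": "BP", "ld_score": "L2"}
    )[["CHR", "SNP", "BP", "L2"]]
    df.to_csv(f"{prefix}.l2.ldscore", sep="\t", index=False)
    with open(f"{prefix}.l2.M", "w") as fh:
        fh.write(f"{ref.M}\n")
    ref.records[["snp", "a1", "a2"]].to_csv(f"{prefix}.alleles", sep="\t", index=False)


def read_ldscores(prefix) -> LDScoreReference:
    """Read an LD score reference written by :func:`write_ldscores`."""
    df = pd.read_csv(f"{prefix}.l2.ldscore", sep="\t", dtype={"CHR": str})
    df = df.rename(columns={"CHR": "chrom", "SNP": "snp", "BP": "pos", "L2": "ld_score"})
    with open(f"{prefix}.l2.M") as fh:
        M = float(fh.read().strip())
    try:
        alleles = pd.read_csv(f"{prefix}.alleles", sep="\t", dtype=str)
        df = df.merge(alleles, on="snp", how="left")
    except FileNotFoundError:
        df["a1"], df["a2"] = "A", "G"
    return LDScoreReference(records=df, M=M)
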