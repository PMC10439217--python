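"""Confirmatory model ladder for the alcohol / life-satisfaction analysis.

Eleven indicators enter the final models: three alcohol-use indicators
(drinks per week and two AUDIT-C measures), four AUD indicators (maximum
habitual alcohol use, AUDIT-P, AUD case/control, alcohol dependence
case/control) and four life-satisfaction items (family, friends, work,
finances). A twelfth indicator, the 23andMe AUDIT total score, is screened
in an initial three-factor model where it cross-loads on both alcohol
factors; it is excluded from the final models when its loading is near zero
and non-significant (it mixes consumption and problems content, so it has no
clean factor home).

The ladder compares:

* LS_only — one factor over the four satisfaction items (sanity model);
* A — one common factor over all 11 items;
* B — correlated alcohol (7) and satisfaction (4) factors;
* C — correlated use (3), AUD (4) and satisfaction (4) factors;
* D — bifactor: a common alcohol factor over all 7 alcohol items plus
  orthogonal unique-use (3) and unique-AUD (3; alcohol dependence loads on
  the common factor only) group factors, with the satisfaction factor free
  to correlate with all three.

Models are judged on CFI >= 0.9 and SRMR <= 0.08 with lower AIC preferred.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gsemkit.covariance import GeneticCovariance
from gsemkit.sem import FREE, FitResult, ModelSpec, fit_dwls


@dataclass
class ItemSet:
    """Item-to-construct assignment for the ladder."""

    alcohol_use: list[str] = field(
        default_factory=lambda: ["DPW", "AUDITC_UKB", "AUDITC_MVP"]
    )
    aud: list[str] = field(
        default_factory=lambda: ["MAXALC", "AUDITP_UKB", "AUD_MVP", "AD_PGC"]
    )
    satisfaction: list[str] = field(
        default_factory=lambda: ["SAT_FAMILY", "SAT_FRIENDS", "SAT_WORK", "SAT_FINANCE"]
    )
    excluded: list[str] = field(default_factory=lambda: ["AUDITT_23ANDME"])
    #: AUD indicators kept on the unique AUD group factor in the bifactor
    #: model; alcohol dependence is restricted to the common factor.
    aud_unique: list[str] = field(
        default_factory=lambda: ["MAXALC", "AUDITP_UKB", "AUD_MVP"]
    )

    @property
    def alcohol(self) -> list[str]:
        return self.alcohol_use + self.aud

    @property
    def all_items(self) -> list[str]:
        return self.alcohol_use + self.aud + self.satisfaction

    def validate(self) -> None:
        items = self.all_items
        if len(items) != len(set(items)):
            raise ValueError("duplicate items across factors")
        if len(items) != 11:
            raise ValueError(f"expected 11 retained items, got {len(items)}")
        for ex in self.excluded:
            if ex in items:
                raise ValueError(f"excluded item {ex!r} appears in the retained set")
        for it in self.aud_unique:
            if it not in self.aud:
                raise ValueError(f"unique-AUD item {it!r} is not an AUD indicator")


DEFAULT_ITEMS = ItemSet()


def build_model(variant: str, items: ItemSet = DEFAULT_ITEMS) -> ModelSpec:
    """Build one of the ladder's model specifications.

    Variants: ``"A"`` common factor, ``"B"`` two correlated factors,
    ``"C"`` three correlated factors, ``"D"`` bifactor, ``"LS_only"``
    one-factor life satisfaction. All factor variances are fixed at 1 so free
    factor covariances are correlations.
    """
    items.validate()
    if variant == "LS_only":
        return ModelSpec(
            name="LS_only",
            items=list(items.satisfaction),
            factors=["LS"],
            loadings={(it, "LS"): FREE for it in items.satisfaction},
        )
    all_items = items.all_items
    if variant == "A":
        return ModelSpec(
            name="A",
            items=all_items,
            factors=["G"],
            loadings={(it, "G"): FREE for it in all_items},
        )
    if variant == "B":
        load = {(it, "ALC"): FREE for it in items.alcohol}
        load.update({(it, "LS"): FREE for it in items.satisfaction})
        return ModelSpec(
            name="B",
            items=all_items,
            factors=["ALC", "LS"],
            loadings=load,
            factor_cov={("LS", "ALC"): FREE},
        )
    if variant == "C":
        load = {(it, "USE"): FREE for it in items.alcohol_use}
        load.update({(it, "AUD"): FREE for it in items.aud})
        load.update({(it, "LS"): FREE for it in items.satisfaction})
        return ModelSpec(
            name="C",
            items=all_items,
            factors=["USE", "AUD", "LS"],
            loadings=load,
            factor_cov={
                ("AUD", "USE"): FREE,
                ("LS", "USE"): FREE,
                ("LS", "AUD"): FREE,
            },
        )
    if variant == "D":
        load = {(it, "COMMON"): FREE for it in items.alcohol}
        load.update({(it, "U_USE"): FREE for it in items.alcohol_use})
        load.update({(it, "U_AUD"): FREE for it in items.aud_unique})
        load.update({(it, "LS"): FREE for it in items.satisfaction})
        return ModelSpec(
            name="D",
            items=all_items,
            factors=["COMMON", "U_USE", "U_AUD", "LS"],
            loadings=load,
            factor_cov={
                # group factors orthogonal to each other and to the general factor
                ("U_USE", "COMMON"): 0.0,
                ("U_AUD", "COMMON"): 0.0,
                ("U_AUD", "U_USE"): 0.0,
                ("LS", "COMMON"): FREE,
                ("LS", "U_USE"): FREE,
                ("LS", "U_AUD"): FREE,
            },
        )
    raise ValueError(f"unknown model variant {variant!r}")


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class ComparisonReport:
    """Ladder outcome: per-model fits, ranking and the decision-rule winner."""

    fits: dict[str, FitResult]
    ranking: list[str]
    selected: str
    rows: list[dict]

    def to_dict(self) -> dict:
        return {
            "selected": self.selected,
            "ranking": self.ranking,
            "models": self.rows,
        }


def run_ladder(
    gc: GeneticCovariance,
    items: ItemSet = DEFAULT_ITEMS,
    cfi_cut: float = 0.9,
    srmr_cut: float = 0.08,
) -> ComparisonReport:
    """Fit LS_only then Models A-D and apply the decision rule.

    Each model is flagged pass/fail on CFI >= cfi_cut and SRMR <= srmr_cut;
    among A-D the lowest-AIC converged model is selected. Factor correlations
    are reported with sandwich SEs and normal-theory significance stars.
    Non-convergence does not stop the ladder; the model is flagged.
    """
    items.validate()
    missing = [t for t in items.all_items if t not in gc.trait_names]
    if missing:
        raise KeyError(f"genetic covariance is missing item(s): {missing}")

    fits: dict[str, FitResult] = {}
    rows: list[dict] = []
    for variant in ["LS_only", "A", "B", "C", "D"]:
        spec = build_model(variant, items)
        fit = fit_dwls(spec, gc)
        fits[variant] = fit
        corr = []
        for name in fit.param_names:
            if name[0] != "psi":
                continue
            p = fit.p_of(name)
            corr.append({
                "factors": [name[1], name[2]],
                "r_g": fit.estimate(name),
                "se": fit.se_of(name),
                "p": p,
                "stars": _stars(p),
            })
        rows.append({
            "model": variant,
            "chisq": fit.chisq,
            "df": fit.df,
            "p_value": fit.p_value,
            "AIC": fit.AIC,
            "CFI": fit.CFI,
            "SRMR": fit.SRMR,
            "converged": fit.converged,
            "fit_ok": (
                fit.CFI is not None
                and fit.CFI >= cfi_cut
                and fit.SRMR is not None
                and fit.SRMR <= srmr_cut
            ),
            "factor_correlations": corr,
        })
    candidates = [v for v in ["A", "B", "C", "D"] if fits[v].converged]
    ranking = sorted(candidates, key=lambda v: fits[v].AIC)
    return ComparisonReport(fits=fits, ranking=ranking, selected=ranking[0], rows=rows)


def initial_model_check(
    gc_with_audit_t: GeneticCovariance,
    items: ItemSet = DEFAULT_ITEMS,
    audit_t: str = "AUDITT_23ANDME",
    loading_threshold: float = 0.10,
    alpha: float = 0.05,
) -> dict:
    """Screen the AUDIT total score in a 12-item three-factor model.

    AUDIT-T cross-loads on both the use and the AUD factor (its items span
    both subscales). For each of its loadings the report states the
    standardized estimate, SE and p-value, and recommends exclusion when at
    least one loading is below ``loading_threshold`` in magnitude and
    non-significant at ``alpha``. With threshold 0 exclusion is never
    recommended.
    """
    items.validate()
    load = {(it, "USE"): FREE for it in items.alcohol_use}
    load.update({(it, "AUD"): FREE for it in items.aud})
    load[(audit_t, "USE")] = FREE
    load[(audit_t, "AUD")] = FREE
    load.update({(it, "LS"): FREE for it in items.satisfaction})
    all_items = items.alcohol_use + [audit_t] + items.aud + items.satisfaction
    spec = ModelSpec(
        name="C_initial",
        items=all_items,
        factors=["USE", "AUD", "LS"],
        loadings=load,
        factor_cov={
            ("AUD", "USE"): FREE,
            ("LS", "USE"): FREE,
            ("LS", "AUD"): FREE,
        },
    )
    fit = fit_dwls(spec, gc_with_audit_t)
    report = {"model": spec.name, "converged": fit.converged, "loadings": [], "recommend_exclusion": False}
    for factor in ["USE", "AUD"]:
        name = ("lambda", audit_t, factor)
        std = fit.standardized_loadings.get((audit_t, factor))
        p = fit.p_of(name)
        near_zero = abs(std) < loading_threshold and (not np.isfinite(p) or p > alpha)
        report["loadings"].append({
            "factor": factor,
            "standardized": std,
            "estimate": fit.estimate(name),
            "se": fit.se_of(name),
            "p": p,
            "near_zero": bool(near_zero),
        })
        if near_zero and loading_threshold > 0:
            report["recommend_exclusion"] = True
    report["fit"] = fit
    return report
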