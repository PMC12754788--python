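"""The two-step Linear-Tobit GWAS scheme.

Step 1 screens every variant with fast linear regression on the
average-tie INT outcome; step 2 groups the significant variants into
LD clumps and refits only the clump leads (or, optionally, every
significant variant) with the Tobit model, whose estimates are not
attenuated by the censoring. The Tobit cost therefore scales with the
number of loci, not the number of variants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import models, transforms
from .simulate import CensoredPhenotype, GenotypeMatrix

__all__ = [
    "ClumpParams",
    "gwas_screen",
    "clump",
    "refine_tobit",
    "linear_tobit_scheme",
]

TABLE_COLUMNS = [
    "variant_id", "position", "maf", "n", "model",
    "beta", "se", "p_value", "converged", "reason",
]


@dataclass(frozen=True)
class ClumpParams:
    """Greedy LD-clumping thresholds (defaults follow common GWAS practice)."""

    p1: float = 5e-8       # index-variant significance threshold
    p2: float = 1e-4       # clump-membership threshold
    r2: float = 0.1        # LD threshold (squared Pearson correlation)
    window_kb: float = 1000.0

    def __post_init__(self) -> None:
        if self.p1 > self.p2:
            raise ValueError("p1 must be <= p2")
        if not 0 < self.r2 <= 1:
            raise ValueError("r2 must lie in (0, 1]")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")


def _prepare_outcome(ph: CensoredPhenotype, model: str):
    if model == "linear":
        return transforms.prepare_linear_outcome(ph)
    if model == "tobit":
        return transforms.prepare_tobit_outcome(ph)
    if model == "cox":
        return transforms.prepare_cox_outcome(ph)
    if model == "logistic":
        return transforms.prepare_logistic_outcome(ph)
    raise ValueError(f"unknown model {model!r}")


def _fit_one(model: str, outcome, design: np.ndarray) -> models.FitResult:
    if model == "linear":
        return models.fit_linear(outcome, design)
    if model == "tobit":
        return models.fit_tobit(outcome, design)
    if model == "cox":
        return models.fit_cox(outcome, design)
    return models.fit_logistic(outcome, design)


def gwas_screen(
    genotypes: GenotypeMatrix,
    phenotype: CensoredPhenotype,
    covariates: np.ndarray | None = None,
    model: str = "linear",
) -> pd.DataFrame:
    """Per-variant association scan with the chosen engine.

    Each variant is fitted against the phenotype preprocessed for the
    engine (the transform does not depend on the variant, so it is computed
    once). Variants failing preconditions (minor allele count below
    ``models.MIN_MINOR_ALLELE_COUNT``) get an NA row with a reason code.
    """
    if genotypes.n_samples != phenotype.n:
        raise ValueError("genotypes and phenotype describe different samples")
    outcome = _prepare_outcome(phenotype, model)
    rows = []
    n_ok = 0
    for j in range(genotypes.n_variants):
        g = genotypes.column(j)
        rec = {
            "variant_id": genotypes.variant_ids[j],
            "position": int(genotypes.positions[j]),
            "maf": float(genotypes.realized_mafs[j]),
            "n": phenotype.n,
            "model": model,
            "beta": np.nan, "se": np.nan, "p_value": np.nan,
            "converged": False, "reason": "",
        }
        mac = min(g.sum(), (2 - g).sum())
        if mac < models.MIN_MINOR_ALLELE_COUNT:
            rec["reason"] = f"mac_lt_{models.MIN_MINOR_ALLELE_COUNT}"
            rows.append(rec)
            continue
        design = models.build_design(g, covariates)
        fit = _fit_one(model, outcome, design)
        rec.update(
            beta=fit.beta, se=fit.se, p_value=fit.p_value,
            converged=fit.converged,
            reason="" if fit.converged else "non_convergence",
        )
        n_ok += 1
        rows.append(rec)
    if n_ok == 0:
        raise ValueError("zero analyzable variants")
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def clump(
    table: pd.DataFrame,
    genotypes: GenotypeMatrix,
    params: ClumpParams = ClumpParams(),
) -> pd.DataFrame:
    """Greedy LD clumping of the screened table.

    Repeatedly take the smallest-p unassigned variant with p < p1 as an
    index; assign to its clump every unassigned variant with p < p2,
    r^2 >= params.r2 against the index, and base-pair distance within the
    window. Ties on p break toward the smaller position. LD is the squared
    Pearson correlation of dosages in the analysis sample itself.
    """
    out = table.copy()
    out["clump_id"] = pd.array([None] * len(out), dtype="string")
    out["is_index"] = False

    col_of = {v: j for j, v in enumerate(genotypes.variant_ids)}
    work = out[["variant_id", "position", "p_value"]].dropna(subset=["p_value"])
    work = work.sort_values(["p_value", "position"], kind="mergesort")

    assigned: set[str] = set()
    dos = genotypes.dosages.astype(float)
    for _, cand in work.iterrows():
        vid = cand["variant_id"]
        if vid in assigned or cand["p_value"] >= params.p1:
            continue
        idx_col = col_of[vid]
        members = [vid]
        assigned.add(vid)
        g_index = dos[:, idx_col]
        for _, other in work.iterrows():
            ovid = other["variant_id"]
            if ovid in assigned or other["p_value"] >= params.p2:
                continue
            if abs(other["position"] - cand["position"]) > params.window_kb * 1000:
                continue
            g_other = dos[:, col_of[ovid]]
            if np.ptp(g_other) == 0:
                continue
            r = np.corrcoef(g_index, g_other)[0, 1]
            if r * r >= params.r2:
                members.append(ovid)
                assigned.add(ovid)
        sel = out["variant_id"].isin(members)
        out.loc[sel, "clump_id"] = vid
        out.loc[out["variant_id"] == vid, "is_index"] = True
    return out


def refine_tobit(
    table: pd.DataFrame,
    genotypes: GenotypeMatrix,
    phenotype: CensoredPhenotype,
    covariates: np.ndarray | None = None,
    variants: list[str] | None = None,
) -> pd.DataFrame:
    """Tobit refit of selected variants; screening fields stay untouched.

    By default the clump index variants are refined. Tobit non-convergence
    is recorded per variant (refined_converged=False), never fatal.
    """
    out = table.copy()
    for col in ("refined_beta", "refined_se", "refined_p"):
        if col not in out.columns:
            out[col] = np.nan
    if "refined_converged" not in out.columns:
        out["refined_converged"] = pd.array([None] * len(out), dtype="boolean")

    if variants is None:
        if "is_index" in out.columns:
            variants = list(out.loc[out["is_index"].fillna(False), "variant_id"])
        else:
            variants = []
    if not variants:
        return out

    outcome = transforms.prepare_tobit_outcome(phenotype)
    col_of = {v: j for j, v in enumerate(genotypes.variant_ids)}
    for vid in variants:
        g = genotypes.column(col_of[vid])
        design = models.build_design(g, covariates)
        fit = models.fit_tobit(outcome, design)
        sel = out["variant_id"] == vid
        out.loc[sel, ["refined_beta", "refined_se", "refined_p"]] = (
            fit.beta, fit.se, fit.p_value,
        )
        out.loc[sel, "refined_converged"] = fit.converged
    return out


def linear_tobit_scheme(
    genotypes: GenotypeMatrix,
    phenotype: CensoredPhenotype,
    covariates: np.ndarray | None = None,
    params: ClumpParams = ClumpParams(),
    refine_all_significant: bool = False,
) -> pd.DataFrame:
    """Linear screen -> LD clump -> Tobit refinement of the leads.

    With ``refine_all_significant`` every variant with p < params.p1 is
    refined instead of the clump indices only.
    """
    table = gwas_screen(genotypes, phenotype, covariates, model="linear")
    table = clump(table, genotypes, params)
    if refine_all_significant:
        sig = table["p_value"] < params.p1
        variants = list(table.loc[sig.fillna(False), "variant_id"])
    else:
        variants = None
    return refine_tobit(table, genotypes, phenotype, covariates, variants)
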