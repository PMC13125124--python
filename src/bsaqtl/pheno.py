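"""Two-stage mixed-model BLUPs, variance components and heritability.

Stage 1 fits ``y = mu + genotype + block + eps`` within each environment
(all effects random, REML) and reports mu + genotype BLUP per RIL as the
*environmental* BLUPs.  Stage 2 fits ``value = mu + genotype +
environment + eps`` on the stage-1 genotype-by-environment estimates and
reports mu + genotype BLUP as the *GEI* BLUPs (with one value per cell,
the interaction is confounded with the stage-2 residual).

Variance components for heritability come from the single plot-level
model ``y = mu + G + E + GEI + block(E) + eps`` fitted by REML, and
broad-sense heritability on an entry-mean basis is

    H^2 = sigma_G^2 / [sigma_G^2 + sigma_GEI^2 / e + sigma_err^2 / (r e)]

with r replications and e environments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._reml import (
    RemlFit,
    blup_two_way,
    reml_from_strata,
    reml_profile_loglik,
    reml_unbalanced,
    strata_plot_model,
    strata_two_way,
)

__all__ = [
    "BlupTable",
    "VarianceComponents",
    "stage1_blups",
    "stage2_blups",
    "compute_blups",
    "variance_components",
    "heritability",
    "trait_correlations",
]

GEI_CONTEXT = "GEI"


@dataclass
class VarianceComponents:
    trait: str
    var_G: float
    var_E: float
    var_GEI: float
    var_block: float
    var_error: float
    r: int
    e: int
    lrt_pvalues: dict[str, float] = field(default_factory=dict)
    converged: bool = True

    def __post_init__(self) -> None:
        for name in ("var_G", "var_E", "var_GEI", "var_block", "var_error"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.r < 1 or self.e < 1:
            raise ValueError("r and e must be >= 1")


@dataclass
class BlupTable:
    """Long table of genotype mean estimates: one row per
    (trait, context, ril) where context is an environment id or "GEI"."""

    table: pd.DataFrame  # columns: trait, context, ril, blup

    def env_blups(self, trait: str) -> pd.DataFrame:
        sub = self.table[(self.table["trait"] == trait) & (self.table["context"] != GEI_CONTEXT)]
        return sub.pivot(index="ril", columns="context", values="blup")

    def gei_blups(self, trait: str) -> pd.Series:
        sub = self.table[(self.table["trait"] == trait) & (self.table["context"] == GEI_CONTEXT)]
        return sub.set_index("ril")["blup"]

    def traits(self) -> list[str]:
        return list(dict.fromkeys(self.table["trait"]))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BlupTable":
        df = pd.read_csv(path, dtype={"ril": str})
        return cls(table=df[["trait", "context", "ril", "blup"]])


def _is_balanced(pivot: pd.DataFrame) -> bool:
    return not pivot.isna().any().any()


def stage1_blups(pheno: pd.DataFrame, environment: str, trait: str) -> pd.Series:
    """Environmental BLUPs (mu + genotype effect) for one environment.

    Balanced genotype-by-block layouts use the exact spectral REML and its
    closed-form shrinkage; unbalanced data fall back to a dense REML with
    Henderson-equation BLUPs.  A single block drops the block term with a
    warning; with one observation per genotype the genotype and error
    variances are confounded and the raw values are returned unshrunken.
    """
    sub = pheno[(pheno["environment"] == environment) & (pheno["trait"] == trait)]
    if sub.empty:
        raise ValueError(f"no data for environment {environment!r}, trait {trait!r}")
    pivot = sub.pivot_table(index="ril", columns="block", values="value", aggfunc="first")
    if len(pivot) < 2:
        raise ValueError("need >= 2 genotypes")
    rils = pivot.index.to_numpy()

    if pivot.shape[1] == 1:
        warnings.warn(
            f"single block in environment {environment!r}: block term dropped, "
            "genotype and error variance confounded; returning unshrunken values",
            stacklevel=2,
        )
        return pd.Series(pivot.iloc[:, 0].to_numpy(), index=rils, name=trait)

    if _is_balanced(pivot):
        y = pivot.to_numpy()
        fit = reml_from_strata(strata_two_way(y, ("genotype", "block")), ["genotype", "block"])
        mu = float(y.mean())
        vg, ve = fit.components["genotype"], fit.sigma_error2
        r = y.shape[1]
        shrink = 0.0 if vg <= 0 else (r * vg) / (r * vg + ve)
        blup = mu + shrink * (y.mean(axis=1) - mu)
    else:
        long = pivot.stack().rename("value").reset_index()
        codes_g = pd.Categorical(long["ril"], categories=rils).codes
        codes_b = pd.Categorical(long["block"]).codes
        yv = long["value"].to_numpy(dtype=float)
        fit = reml_unbalanced(yv, {"genotype": codes_g, "block": codes_b})
        if not fit.converged:
            raise RuntimeError(
                f"stage-1 REML failed to converge (env {environment!r}, trait {trait!r}): "
                f"components={fit.components}, sigma_e2={fit.sigma_error2}"
            )
        mu, u = blup_two_way(
            yv, codes_g, codes_b, fit.components["genotype"], fit.components["block"], fit.sigma_error2
        )
        blup = mu + u
    return pd.Series(blup, index=rils, name=trait)


def stage2_blups(env_blups: pd.DataFrame, trait: str) -> pd.Series:
    """GEI BLUPs (mu + genotype effect) from the genotype-by-environment
    table of stage-1 estimates (rows = RILs, columns = environments)."""
    if env_blups.shape[1] < 2:
        raise ValueError("need environmental BLUPs for >= 2 environments")
    rils = env_blups.index.to_numpy()
    if _is_balanced(env_blups):
        y = env_blups.to_numpy()
        fit = reml_from_strata(strata_two_way(y, ("genotype", "environment")), ["genotype", "environment"])
        mu = float(y.mean())
        vg, ve = fit.components["genotype"], fit.sigma_error2
        e = y.shape[1]
        shrink = 0.0 if vg <= 0 else (e * vg) / (e * vg + ve)
        blup = mu + shrink * (y.mean(axis=1) - mu)
    else:
        long = env_blups.stack().rename("value").reset_index()
        long.columns = ["ril", "environment", "value"]
        codes_g = pd.Categorical(long["ril"], categories=rils).codes
        codes_e = pd.Categorical(long["environment"]).codes
        yv = long["value"].to_numpy(dtype=float)
        fit = reml_unbalanced(yv, {"genotype": codes_g, "environment": codes_e})
        mu, u = blup_two_way(
            yv, codes_g, codes_e, fit.components["genotype"], fit.components["environment"], fit.sigma_error2
        )
        blup = mu + u
    return pd.Series(blup, index=rils, name=trait)


def compute_blups(pheno: pd.DataFrame, traits: list[str] | None = None) -> BlupTable:
    """Run both stages for every trait and assemble a :class:`BlupTable`."""
    traits = traits or list(dict.fromkeys(pheno["trait"]))
    environments = list(dict.fromkeys(pheno["environment"]))
    rows = []
    for trait in traits:
        stage1 = {}
        for env in environments:
            s = stage1_blups(pheno, env, trait)
            stage1[env] = s
            rows.extend({"trait": trait, "context": env, "ril": r, "blup": v} for r, v in s.items())
        env_tab = pd.DataFrame(stage1)
        gei = stage2_blups(env_tab, trait)
        rows.extend({"trait": trait, "context": GEI_CONTEXT, "ril": r, "blup": v} for r, v in gei.items())
    return BlupTable(table=pd.DataFrame(rows))


def variance_components(pheno: pd.DataFrame, trait: str, lrt: bool = True) -> VarianceComponents:
    """REML variance components of the plot-level model
    ``y = mu + G + E + GEI + block(E) + eps`` plus boundary-corrected
    likelihood-ratio p-values per random term.

    The LRT reference is the 50:50 mixture 0.5*chi2_0 + 0.5*chi2_1, the
    standard correction for testing a variance on its boundary.
    """
    sub = pheno[pheno["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no data for trait {trait!r}")
    rils = sorted(sub["ril"].unique())
    envs = sorted(sub["environment"].unique())
    blocks = sorted(sub["block"].unique())
    g, e, r = len(rils), len(envs), len(blocks)
    names = ["genotype", "environment", "gei", "block"]

    cube = (
        sub.set_index(["ril", "environment", "block"])["value"]
        .reindex(pd.MultiIndex.from_product([rils, envs, blocks]))
        .to_numpy()
        .reshape(g, e, r)
    )
    balanced = not np.isnan(cube).any() and g > 1 and e > 1 and r > 1
    if balanced:
        strata = strata_plot_model(cube)
        fit = reml_from_strata(strata, names)
        pvals = {}
        if lrt:
            for term in names:
                fit0 = reml_profile_loglik(strata, names, {term: 0.0})
                lr = max(0.0, 2.0 * (fit.loglik - fit0.loglik))
                pvals[term] = 1.0 if lr <= 0 else 0.5 * stats.chi2.sf(lr, df=1)
    else:
        codes_g = pd.Categorical(sub["ril"], categories=rils).codes
        codes_e = pd.Categorical(sub["environment"], categories=envs).codes
        codes_ge = codes_g * e + codes_e
        codes_eb = codes_e * r + pd.Categorical(sub["block"], categories=blocks).codes
        yv = sub["value"].to_numpy(dtype=float)
        factors = {"genotype": codes_g, "environment": codes_e, "gei": codes_ge, "block": codes_eb}
        fit = reml_unbalanced(yv, factors)
        pvals = {}
        if lrt:
            for term in names:
                reduced = {k: v for k, v in factors.items() if k != term}
                fit0 = reml_unbalanced(yv, reduced)
                lr = max(0.0, 2.0 * (fit.loglik - fit0.loglik))
                pvals[term] = 1.0 if lr <= 0 else 0.5 * stats.chi2.sf(lr, df=1)

    return VarianceComponents(
        trait=trait,
        var_G=max(0.0, fit.components["genotype"]),
        var_E=max(0.0, fit.components["environment"]),
        var_GEI=max(0.0, fit.components["gei"]),
        var_block=max(0.0, fit.components["block"]),
        var_error=max(0.0, fit.sigma_error2),
        r=r,
        e=e,
        lrt_pvalues=pvals,
        converged=fit.converged,
    )


def heritability(vc: VarianceComponents) -> float:
    """Entry-mean broad-sense heritability
    ``var_G / [var_G + var_GEI/e + var_error/(r*e)]``; in [0, 1] for
    non-negative components."""
    denom = vc.var_G + vc.var_GEI / vc.e + vc.var_error / (vc.r * vc.e)
    if denom <= 0:
        raise ZeroDivisionError("heritability undefined: all variance components are zero")
    return vc.var_G / denom


def trait_correlations(blups: BlupTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations (and two-sided t-test p-values) of the
    GEI BLUPs across traits.  Zero-variance traits yield NaN entries."""
    traits = blups.traits()
    mat = pd.DataFrame({t: blups.gei_blups(t) for t in traits})
    if len(mat) < 3:
        raise ValueError("need >= 3 RILs with BLUPs")
    k = len(traits)
    rmat = pd.DataFrame(np.eye(k), index=traits, columns=traits)
    pmat = pd.DataFrame(np.zeros((k, k)), index=traits, columns=traits)
    for i in range(k):
        for j in range(i + 1, k):
            x, y = mat.iloc[:, i], mat.iloc[:, j]
            ok = x.notna() & y.notna()
            if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
                r_, p_ = np.nan, np.nan
            else:
                r_, p_ = stats.pearsonr(x[ok], y[ok])
            rmat.iloc[i, j] = rmat.iloc[j, i] = r_
            pmat.iloc[i, j] = pmat.iloc[j, i] = p_
    return rmat, pmat
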