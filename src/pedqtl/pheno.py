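"""Variance decomposition, broad-sense heritability and trait correlations.

The trial design is genotypes x environments with (possibly unequal)
replication within environment. Replicate values are averaged per
(genotype, environment) cell first, and the two-way crossed ANOVA runs on
the resulting mean table; with one observation per cell the interaction is
confounded with error, so the residual mean square is the error term.

Variance components come from the expected-mean-squares (method-of-moments)
solution and broad-sense heritability is

    H^2 = var_g / (var_g + var_e + var_resid)

i.e. genotypic variance over total phenotypic variance across environments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .core import ConfigError, PhenotypeTable


@dataclass
class AnovaResult:
    ms_genotype: float
    ms_environment: float
    ms_error: float
    df_genotype: int
    df_environment: int
    df_error: int
    f_genotype: float  # MS_G / MS_error; NaN when MS_error = 0
    f_environment: float
    n_genotypes: int
    n_environments: int
    balanced: bool


@dataclass
class VarianceComponents:
    var_g: float
    var_e: float
    var_resid: float
    n_genotypes: int
    n_environments: int
    truncated: list[str]  # components clamped to 0 from a negative estimate


def two_way_anova(pheno: PhenotypeTable, trait: str) -> AnovaResult:
    """Two-way crossed ANOVA (genotype, environment) on the cell-mean table.

    Missing cells are handled by a one-step unweighted-means fill (row mean
    + column mean - grand mean) with the error degrees of freedom reduced by
    the number of filled cells; the result is flagged unbalanced.
    """
    cell = pheno.env_means(trait)  # raises if trait absent
    g, e = cell.shape
    if g < 2 or e < 2:
        raise ConfigError("need at least 2 genotypes and 2 environments")
    values = cell.to_numpy(dtype=float)
    n_missing = int(np.isnan(values).sum())
    balanced = n_missing == 0
    if not balanced:
        warnings.warn(f"{n_missing} missing (genotype, environment) cells; unweighted-means fill")
        row = np.nanmean(values, axis=1, keepdims=True)
        col = np.nanmean(values, axis=0, keepdims=True)
        grand = np.nanmean(values)
        fill = row + col - grand
        values = np.where(np.isnan(values), fill, values)

    grand = values.mean()
    ss_g = e * ((values.mean(axis=1) - grand) ** 2).sum()
    ss_e = g * ((values.mean(axis=0) - grand) ** 2).sum()
    ss_tot = ((values - grand) ** 2).sum()
    ss_err = ss_tot - ss_g - ss_e
    df_g, df_e = g - 1, e - 1
    df_err = df_g * df_e - n_missing
    if df_err < 1:
        raise ConfigError("no residual degrees of freedom")
    ms_g = ss_g / df_g
    ms_e = ss_e / df_e
    ms_err = max(ss_err, 0.0) / df_err
    f_g = ms_g / ms_err if ms_err > 0 else math.nan
    f_e = ms_e / ms_err if ms_err > 0 else math.nan
    return AnovaResult(ms_g, ms_e, ms_err, df_g, df_e, df_err, f_g, f_e, g, e, balanced)


def variance_components(anova: AnovaResult) -> VarianceComponents:
    """Expected-mean-squares solution of the two-way random-effects model.

    var_resid = MS_err; var_g = (MS_G - MS_err) / n_env;
    var_e = (MS_E - MS_err) / n_geno. Negative estimates are truncated to 0
    and flagged.
    """
    if anova.n_genotypes < 2 or anova.n_environments < 2:
        raise ConfigError("need at least 2 genotypes and 2 environments")
    truncated = []
    var_resid = anova.ms_error
    var_g = (anova.ms_genotype - anova.ms_error) / anova.n_environments
    var_e = (anova.ms_environment - anova.ms_error) / anova.n_genotypes
    if var_g < 0:
        var_g, _ = 0.0, truncated.append("var_g")
    if var_e < 0:
        var_e, _ = 0.0, truncated.append("var_e")
    return VarianceComponents(
        var_g, var_e, var_resid, anova.n_genotypes, anova.n_environments, truncated
    )


def broad_sense_heritability(vc: VarianceComponents) -> float:
    """H^2 = var_g / (var_g + var_e + var_resid); NaN when all components are 0."""
    total = vc.var_g + vc.var_e + vc.var_resid
    if total == 0:
        return math.nan
    return vc.var_g / total


def heritability_from_mean_squares(
    ms_genotype: float,
    ms_environment: float,
    ms_error: float,
    n_genotypes: int,
    n_environments: int,
) -> tuple[VarianceComponents, float]:
    """Convenience: variance components and H^2 straight from printed mean squares."""
    anova = AnovaResult(
        ms_genotype,
        ms_environment,
        ms_error,
        n_genotypes - 1,
        n_environments - 1,
        (n_genotypes - 1) * (n_environments - 1),
        ms_genotype / ms_error if ms_error > 0 else math.nan,
        ms_environment / ms_error if ms_error > 0 else math.nan,
        n_genotypes,
        n_environments,
        True,
    )
    vc = variance_components(anova)
    return vc, broad_sense_heritability(vc)


def env_correlations(
    pheno: PhenotypeTable, trait: str, min_shared: int = 3
) -> tuple[pd.DataFrame, pd.Series]:
    """Pearson correlations among environments and per-accession genotypic values.

    Correlations use pairwise-complete accessions; a pair sharing fewer than
    ``min_shared`` accessions gets a missing cell with a warning. The
    genotypic value is the accession's mean over environments.
    """
    cell = pheno.env_means(trait)
    if cell.shape[1] < 2:
        raise ConfigError("need at least 2 environments")
    corr = cell.corr(method="pearson", min_periods=min_shared)
    n_shared = cell.notna().astype(int).T @ cell.notna().astype(int)
    thin = (n_shared < min_shared) & ~np.eye(len(corr), dtype=bool)
    if thin.to_numpy().any():
        warnings.warn("environment pairs with fewer than "
                      f"{min_shared} shared accessions reported as missing")
    genotypic = cell.mean(axis=1)
    genotypic.name = trait
    return corr, genotypic


def stratified_trait_correlations(
    pheno: PhenotypeTable,
    traits: list[str],
    kernel_type: pd.Series,
    min_stratum: int = 3,
) -> pd.DataFrame:
    """Pairwise trait correlations overall and within kernel-type strata.

    Correlations are computed on genotypic values (environment means).
    ``kernel_type`` maps accession -> 0 (soft) or 1 (hard) and must cover
    every accession used. Strata smaller than ``min_stratum`` yield missing
    values with a warning. Returns rows (trait_a, trait_b, r_overall,
    r_soft, r_hard).
    """
    values = pd.DataFrame({t: pheno.genotypic_values(t) for t in traits})
    uncovered = set(values.index) - set(kernel_type.index)
    if uncovered:
        raise ConfigError(f"kernel type unknown for accessions: {sorted(uncovered)[:5]}")
    kt = kernel_type.reindex(values.index)

    def _r(sub: pd.DataFrame, a: str, b: str) -> float:
        sub = sub[[a, b]].dropna()
        if len(sub) < min_stratum:
            warnings.warn(f"stratum with {len(sub)} accessions for ({a}, {b}); reported missing")
            return math.nan
        if sub[a].std() == 0 or sub[b].std() == 0:
            return math.nan
        return float(stats.pearsonr(sub[a], sub[b])[0])

    rows = []
    for a, b in combinations(traits, 2):
        rows.append(
            {
                "trait_a": a,
                "trait_b": b,
                "r_overall": _r(values, a, b),
                "r_soft": _r(values[kt == 0], a, b),
                "r_hard": _r(values[kt == 1], a, b),
            }
        )
    return pd.DataFrame(rows)


def anova_report(anova: AnovaResult, vc: VarianceComponents, h2: float) -> str:
    """Delimited-text report of the ANOVA table, components and H^2."""
    lines = [
        "term\tdf\tmean_square\tF",
        f"genotype\t{anova.df_genotype}\t{anova.ms_genotype:.4f}\t{anova.f_genotype:.4f}",
        f"environment\t{anova.df_environment}\t{anova.ms_environment:.4f}\t{anova.f_environment:.4f}",
        f"error\t{anova.df_error}\t{anova.ms_error:.4f}\t",
        "",
        "component\tvalue",
        f"var_g\t{vc.var_g:.4f}",
        f"var_e\t{vc.var_e:.4f}",
        f"var_resid\t{vc.var_resid:.4f}",
        f"H2\t{h2:.4f}",
    ]
    return "\n".join(lines) + "\n"
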