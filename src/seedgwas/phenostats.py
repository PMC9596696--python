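"""Replicated multi-environment phenotype statistics.

The combined analysis of variance for a balanced genotype x environment
trial with replicates nested in environments decomposes the total sum of
squares into Env, Rep(Env), Gen, Gen x Env and Error.  Environments are
treated as fixed and genotypes as random, which fixes the F-ratio
denominators: genotypes are tested against the interaction, the
interaction and Rep(Env) against the error, and environments against
Rep(Env).  The expected-mean-square equations then give the variance
components

    s2_e  = MS_Err
    s2_ge = (MS_GxE - MS_Err) / r
    s2_g  = (MS_Gen - MS_GxE) / (e r)

(negative solutions clamped to zero and flagged) and the entry-mean
broad-sense heritability H2 = s2_g / (s2_g + s2_ge/e + s2_e/(e r)).
A per-environment variant H2 = s2_g / (s2_g + s2_e/r) from the one-
environment Gen x Rep ANOVA is also provided, because published tables
sometimes print H2 per environment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UnbalancedDesign

__all__ = [
    "AnovaTable",
    "VarianceComponents",
    "combined_anova",
    "single_env_anova",
    "variance_components",
    "heritability",
    "heritability_per_env",
    "correlation_matrix",
    "summary_stats",
    "significance_code",
]


def significance_code(p: float) -> str:
    """ns / * / ** / *** at the 5%, 1% and 0.1% probability levels."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class AnovaTable:
    """Combined ANOVA rows plus the design sizes (g genotypes, e
    environments, r replicates)."""

    table: pd.DataFrame
    g: int
    e: int
    r: int

    def ms(self, source: str) -> float:
        return float(self.table.loc[self.table["source"] == source, "MS"].iloc[0])


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_ge: float
    sigma2_e: float
    e: int
    r: int
    clamped: bool = False


def _pivot_balanced(table: pd.DataFrame, trait: str) -> np.ndarray:
    """(genotype, env, rep) value cube; raises UnbalancedDesign on holes."""
    sub = table[table["trait"] == trait] if "trait" in table.columns else table
    if sub.empty:
        raise ValueError(f"no observations for trait {trait!r}")
    cube = sub.pivot_table(index="accession", columns=["env", "rep"],
                           values="value", aggfunc="count")
    counts = cube.to_numpy()
    if np.isnan(counts).any() or not (counts == 1).all():
        raise UnbalancedDesign(
            "genotype x environment x replicate layout has missing or "
            "duplicated cells")
    wide = sub.pivot_table(index="accession", columns=["env", "rep"],
                           values="value")
    g = wide.shape[0]
    envs = wide.columns.get_level_values(0).unique()
    reps = wide.columns.get_level_values(1).unique()
    arr = np.empty((g, len(envs), len(reps)))
    for j, env in enumerate(envs):
        arr[:, j, :] = wide[env].to_numpy()
    return arr


def combined_anova(table: pd.DataFrame, trait: str) -> AnovaTable:
    """Combined two-factor ANOVA with replicates nested in environments.

    ``table`` is long format with columns accession, env, rep, trait,
    value (or no trait column for a single-trait table).  The layout must
    be balanced.
    """
    y = _pivot_balanced(table, trait)
    g, e, r = y.shape
    grand = y.mean()

    mean_env = y.mean(axis=(0, 2))           # per environment
    mean_rep = y.mean(axis=0)                # per (env, rep)
    mean_gen = y.mean(axis=(1, 2))           # per genotype
    mean_ge = y.mean(axis=2)                 # per (genotype, env)

    ss_env = g * r * np.sum((mean_env - grand) ** 2)
    ss_rep = g * np.sum((mean_rep - mean_env[:, None]) ** 2)
    ss_gen = e * r * np.sum((mean_gen - grand) ** 2)
    ss_ge = r * np.sum((mean_ge - mean_gen[:, None] - mean_env[None, :]
                        + grand) ** 2)
    ss_err = np.sum((y - mean_ge[:, :, None] - mean_rep[None, :, :]
                     + mean_env[None, :, None]) ** 2)
    ss_tot = np.sum((y - grand) ** 2)

    df = {
        "Env": e - 1,
        "Rep(Env)": e * (r - 1),
        "Gen": g - 1,
        "GenxEnv": (g - 1) * (e - 1),
        "Error": (g - 1) * e * (r - 1),
    }
    ss = {"Env": ss_env, "Rep(Env)": ss_rep, "Gen": ss_gen,
          "GenxEnv": ss_ge, "Error": ss_err}
    ms = {k: ss[k] / df[k] for k in ss}

    # fixed environments, random genotypes -> denominators
    fnum = {
        "Env": ("Rep(Env)",),
        "Rep(Env)": ("Error",),
        "Gen": ("GenxEnv",),
        "GenxEnv": ("Error",),
    }
    rows = []
    for src in ["Env", "Rep(Env)", "Gen", "GenxEnv", "Error"]:
        row = {"source": src, "df": df[src], "SS": ss[src], "MS": ms[src],
               "F": np.nan, "p": np.nan, "sig": ""}
        if src in fnum:
            denom = fnum[src][0]
            F = ms[src] / ms[denom]
            p = stats.f.sf(F, df[src], df[denom])
            row.update(F=F, p=p, sig=significance_code(p))
        rows.append(row)
    out = pd.DataFrame(rows)
    assert abs(out["SS"].sum() - ss_tot) <= 1e-8 * max(ss_tot, 1.0)
    return AnovaTable(table=out, g=g, e=e, r=r)


def single_env_anova(table: pd.DataFrame, trait: str, env: str) -> AnovaTable:
    """Gen x Rep ANOVA within one environment (for per-environment H2)."""
    sub = table[table["env"] == env]
    y = _pivot_balanced(sub, trait)  # (g, 1, r)
    g, _, r = y.shape
    y = y[:, 0, :]
    grand = y.mean()
    mean_gen = y.mean(axis=1)
    mean_rep = y.mean(axis=0)
    ss_gen = r * np.sum((mean_gen - grand) ** 2)
    ss_rep = g * np.sum((mean_rep - grand) ** 2)
    ss_err = np.sum((y - mean_gen[:, None] - mean_rep[None, :] + grand) ** 2)
    df = {"Rep": r - 1, "Gen": g - 1, "Error": (g - 1) * (r - 1)}
    ss = {"Rep": ss_rep, "Gen": ss_gen, "Error": ss_err}
    ms = {k: ss[k] / df[k] for k in ss}
    rows = []
    for src in ["Rep", "Gen", "Error"]:
        row = {"source": src, "df": df[src], "SS": ss[src], "MS": ms[src],
               "F": np.nan, "p": np.nan, "sig": ""}
        if src != "Error":
            F = ms[src] / ms["Error"]
            p = stats.f.sf(F, df[src], df["Error"])
            row.update(F=F, p=p, sig=significance_code(p))
        rows.append(row)
    return AnovaTable(table=pd.DataFrame(rows), g=g, e=1, r=r)


def variance_components(anova: AnovaTable) -> VarianceComponents:
    """EMS solution of the combined ANOVA; negatives clamped and flagged."""
    e, r = anova.e, anova.r
    ms_err = anova.ms("Error")
    ms_ge = anova.ms("GenxEnv")
    ms_gen = anova.ms("Gen")
    s2_ge_raw = (ms_ge - ms_err) / r
    s2_g_raw = (ms_gen - ms_ge) / (e * r)
    clamped = s2_ge_raw < 0 or s2_g_raw < 0
    return VarianceComponents(
        sigma2_g=max(0.0, s2_g_raw),
        sigma2_ge=max(0.0, s2_ge_raw),
        sigma2_e=ms_err,
        e=e, r=r, clamped=clamped,
    )


def heritability(vc: VarianceComponents) -> float:
    """Entry-mean broad-sense H2 = s2_g / (s2_g + s2_ge/e + s2_e/(e r)).

    Returns NaN (undefined) when every component is zero.
    """
    denom = vc.sigma2_g + vc.sigma2_ge / vc.e + vc.sigma2_e / (vc.e * vc.r)
    if denom == 0:
        return float("nan")
    return vc.sigma2_g / denom


def heritability_per_env(anova: AnovaTable) -> float:
    """Per-environment H2 = s2_g / (s2_g + s2_e/r) from a Gen x Rep ANOVA."""
    r = anova.r
    ms_err = anova.ms("Error")
    s2_g = max(0.0, (anova.ms("Gen") - ms_err) / r)
    denom = s2_g + ms_err / r
    return s2_g / denom if denom > 0 else float("nan")


def correlation_matrix(wide: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlations with two-sided p-values.

    ``wide`` has one column per trait.  p-values use the t transform with
    n-2 df; pairs against a constant trait are NaN (undefined) in both
    matrices.  Returns (r matrix, p matrix).
    """
    traits = [c for c in wide.columns if pd.api.types.is_numeric_dtype(wide[c])]
    k = len(traits)
    R = np.full((k, k), np.nan)
    P = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            x, y = wide[traits[i]], wide[traits[j]]
            ok = x.notna() & y.notna()
            if ok.sum() < 3:
                continue
            xs, ys = x[ok].to_numpy(), y[ok].to_numpy()
            if xs.std() == 0 or ys.std() == 0:
                if i == j and xs.std() > 0:
                    R[i, j], P[i, j] = 1.0, 0.0
                continue
            if i == j:
                R[i, j], P[i, j] = 1.0, 0.0
            else:
                r, p = stats.pearsonr(xs, ys)
                R[i, j] = R[j, i] = r
                P[i, j] = P[j, i] = p
    rdf = pd.DataFrame(R, index=traits, columns=traits)
    pdf = pd.DataFrame(P, index=traits, columns=traits)
    return rdf, pdf


def summary_stats(wide: pd.DataFrame) -> pd.DataFrame:
    """Per-trait mean, sample sd, CV% and box-plot quartiles.

    CV = 100 * sd / mean (NaN-flagged when the mean is zero); quartiles by
    linear interpolation.
    """
    rows = []
    for trait in wide.columns:
        x = wide[trait].dropna().to_numpy(dtype=float)
        if len(x) < 2:
            raise ValueError(f"trait {trait!r} needs >= 2 observations")
        mean = x.mean()
        sd = x.std(ddof=1)
        cv = 100.0 * sd / mean if mean != 0 else float("nan")
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        rows.append({"trait": trait, "n": len(x), "mean": mean, "sd": sd,
                     "cv_pct": cv, "min": x.min(), "q1": q1, "median": med,
                     "q3": q3, "max": x.max()})
    return pd.DataFrame(rows)
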