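"""Correlation, repeatability and QTL-support statistics.

Implements the downstream quantitative analyses run on extracted traits:

* Pearson/Spearman trait correlations, optionally on the log-log scale
  (the standard allometric model for biomass relationships).
* Variance components for the random-effects model

      y_ijk = mu + G_i + E_j + B_k(j) + GE_ij + R_ijk

  (genotype, environment, replication-within-environment, genotype x
  environment, residual), estimated by exact ANOVA method-of-moments on
  balanced designs and by REML (statsmodels MixedLM) otherwise, with
  negative estimates truncated at zero.
* Repeatability on an entry-mean basis,
  R = sigma2_G / (sigma2_G + sigma2_GxE/t + sigma2_R/(r*t)), and per
  environment, R = sigma2_G / (sigma2_G + sigma2_R/r), where t and r are
  harmonic means of environment and replication counts.
* QTL support: percent variance explained from a LOD score,
  PVE = 100 * (1 - 10^(-2*LOD/n)) for an n-individual population, and the
  physical width (Mb) of a 1.5-LOD support interval from its flanking
  marker names (format S{chromosome}_{bp}).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "correlation_pair",
    "VarianceComponents",
    "RepeatabilityResult",
    "estimate_variance_components",
    "repeatability",
    "repeatability_analysis",
    "harmonic_design_means",
    "pve_from_lod",
    "parse_marker",
    "lod_interval_width_mb",
    "load_qtl_table",
    "qtl_support_table",
]

_REQUIRED_COLS = ("genotype", "environment", "replication")


# ----------------------------------------------------------- correlations

def correlation_pair(x, y, log_log: bool = False) -> tuple[float, float]:
    """Pearson r and Spearman rho between two trait vectors.

    With ``log_log=True`` both variables are natural-log transformed first
    (allometric scale); Spearman is rank-based and therefore unchanged by
    the monotone transform, but is computed on the transformed values for
    consistency.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 paired finite values")
    if log_log:
        if (x <= 0).any() or (y <= 0).any():
            raise ValueError("log-log correlation requires positive values")
        x, y = np.log(x), np.log(y)
    r = float(stats.pearsonr(x, y).statistic)
    rho = float(stats.spearmanr(x, y).statistic)
    return r, rho


# ------------------------------------------------------ variance components

@dataclass
class VarianceComponents:
    var_G: float
    var_E: float
    var_B: float
    var_GxE: float
    var_R: float
    method: str
    gxe_defined: bool = True
    anova_p: dict = field(default_factory=dict)


@dataclass
class RepeatabilityResult:
    components: VarianceComponents
    t_harmonic: float
    r_harmonic: float
    R_overall: float
    R_per_env: dict


def _check_table(table: pd.DataFrame, trait: str) -> pd.DataFrame:
    missing = [c for c in (*_REQUIRED_COLS, trait) if c not in table.columns]
    if missing:
        raise ValueError(f"observation table missing columns: {missing}")
    df = table.dropna(subset=[trait]).copy()
    if df["genotype"].nunique() < 2:
        raise ValueError("need at least 2 genotypes")
    return df


def _is_balanced(df: pd.DataFrame) -> bool:
    """Balanced here: every genotype seen once in every (environment,
    replication) cell, with identical replication sets across environments."""
    counts = df.groupby(["genotype", "environment", "replication"],
                        observed=True).size()
    if (counts != 1).any():
        return False
    g = df["genotype"].nunique()
    t = df["environment"].nunique()
    reps = df.groupby("environment", observed=True)["replication"].nunique()
    if reps.nunique() != 1:
        return False
    r = int(reps.iloc[0])
    return len(df) == g * t * r


def _mom_balanced(df: pd.DataFrame, trait: str) -> VarianceComponents:
    """Exact ANOVA expected-mean-squares estimators on a balanced design."""
    y = df[trait].to_numpy(dtype=float)
    g = df["genotype"].nunique()
    t = df["environment"].nunique()
    r = df.groupby("environment", observed=True)["replication"].nunique().iloc[0]
    grand = y.mean()

    m_g = df.groupby("genotype", observed=True)[trait].mean()
    m_e = df.groupby("environment", observed=True)[trait].mean()
    m_ge = df.groupby(["genotype", "environment"], observed=True)[trait].mean()
    m_eb = df.groupby(["environment", "replication"], observed=True)[trait].mean()

    ss_total = float(((y - grand) ** 2).sum())
    ss_g = r * t * float(((m_g - grand) ** 2).sum())

    if t == 1:
        # single environment: y = mu + G + B + R; GxE not estimable
        ss_b = g * float(((m_eb - grand) ** 2).sum())
        ss_r = ss_total - ss_g - ss_b
        df_g, df_b, df_r = g - 1, r - 1, (g - 1) * (r - 1)
        ms_g = ss_g / df_g
        ms_b = ss_b / df_b if df_b > 0 else 0.0
        ms_r = ss_r / df_r if df_r > 0 else 0.0
        var_R = max(ms_r, 0.0)
        return VarianceComponents(
            var_G=max((ms_g - ms_r) / r, 0.0),
            var_E=0.0,
            var_B=max((ms_b - ms_r) / g, 0.0) if df_b > 0 else 0.0,
            var_GxE=float("nan"),
            var_R=var_R,
            method="anova-mom", gxe_defined=False,
        )

    ss_e = g * r * float(((m_e - grand) ** 2).sum())
    dev_eb = m_eb - m_eb.groupby("environment", observed=True).transform("mean") \
        if r > 1 else m_eb * 0.0
    ss_b = g * float((dev_eb ** 2).sum())
    ge_dev = (m_ge
              - m_ge.index.get_level_values("genotype").map(m_g).to_numpy()
              - m_ge.index.get_level_values("environment").map(m_e).to_numpy()
              + grand)
    ss_ge = r * float((ge_dev ** 2).sum())
    ss_r = ss_total - ss_g - ss_e - ss_b - ss_ge

    df_g = g - 1
    df_e = t - 1
    df_b = t * (r - 1)
    df_ge = (g - 1) * (t - 1)
    df_r = (g - 1) * (r - 1) * t

    ms_g = ss_g / df_g
    ms_e = ss_e / df_e
    ms_b = ss_b / df_b if df_b > 0 else 0.0
    ms_ge = ss_ge / df_ge
    ms_r = ss_r / df_r if df_r > 0 else 0.0

    if df_r == 0:
        # one replication: residual confounded with GxE
        warnings.warn("single replication: residual confounded with GxE")
        var_R = 0.0
        var_ge = max((ms_ge - 0.0) / r, 0.0)
    else:
        var_R = max(ms_r, 0.0)
        var_ge = max((ms_ge - ms_r) / r, 0.0)
    return VarianceComponents(
        var_G=max((ms_g - ms_ge) / (r * t), 0.0),
        var_E=max((ms_e - ms_b - ms_ge + ms_r) / (g * r), 0.0),
        var_B=max((ms_b - ms_r) / g, 0.0) if df_b > 0 else 0.0,
        var_GxE=var_ge,
        var_R=var_R,
        method="anova-mom",
    )


def _reml_unbalanced(df: pd.DataFrame, trait: str) -> VarianceComponents:
    """MixedLM REML with variance-component formulas (unbalanced designs)."""
    import statsmodels.formula.api as smf

    data = df.rename(columns={trait: "_y"}).copy()
    single_env = data["environment"].nunique() < 2
    vc = {"G": "0 + C(genotype)"}
    if not single_env:
        vc["E"] = "0 + C(environment)"
        vc["GE"] = "0 + C(genotype):C(environment)"
    if data.groupby("environment", observed=True)["replication"].nunique().max() > 1:
        vc["B"] = "0 + C(environment):C(replication)"
    data["_grp"] = 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("_y ~ 1", data, groups="_grp",
                            vc_formula=vc, re_formula="0")
        fit = model.fit(reml=True, method="lbfgs", maxiter=300)
    comp = dict(zip(model.exog_vc.names, np.maximum(fit.vcomp, 0.0)))
    return VarianceComponents(
        var_G=float(comp.get("G", 0.0)),
        var_E=float(comp.get("E", 0.0)),
        var_B=float(comp.get("B", 0.0)),
        var_GxE=float(comp.get("GE", np.nan)) if not single_env else float("nan"),
        var_R=float(max(fit.scale, 0.0)),
        method="reml", gxe_defined=not single_env,
    )


def _anova_significance(df: pd.DataFrame, trait: str) -> dict:
    """Two-way ANOVA p-values for genotype, environment and their interaction."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = df.rename(columns={trait: "_y"})
    if data["environment"].nunique() < 2:
        fit = smf.ols("_y ~ C(genotype)", data=data).fit()
        tab = sm.stats.anova_lm(fit, typ=2)
        return {"G": float(tab.loc["C(genotype)", "PR(>F)"])}
    fit = smf.ols(
        "_y ~ C(genotype) + C(environment) + C(genotype):C(environment)",
        data=data).fit()
    tab = sm.stats.anova_lm(fit, typ=2)
    return {
        "G": float(tab.loc["C(genotype)", "PR(>F)"]),
        "E": float(tab.loc["C(environment)", "PR(>F)"]),
        "GxE": float(tab.loc["C(genotype):C(environment)", "PR(>F)"]),
    }


def estimate_variance_components(
    table: pd.DataFrame, trait: str, anova: bool = True
) -> VarianceComponents:
    """Estimate the variance components of the G/E/B(E)/GxE/R model.

    Balanced designs use exact ANOVA method-of-moments (unbiased);
    unbalanced ones fall back to REML.  Negative estimates are truncated
    at zero.  ``anova=True`` also attaches two-way ANOVA p-values for
    genotype, environment and GxE.
    """
    df = _check_table(table, trait)
    if _is_balanced(df):
        comp = _mom_balanced(df, trait)
    else:
        comp = _reml_unbalanced(df, trait)
    if not comp.gxe_defined:
        warnings.warn("single environment: GxE component undefined")
    if anova:
        comp.anova_p = _anova_significance(df, trait)
    return comp


def harmonic_design_means(table: pd.DataFrame, trait: str | None = None
                          ) -> tuple[float, float]:
    """Harmonic means t (environments per genotype) and r (replications per
    genotype-environment cell), tolerant of missing observations."""
    df = table if trait is None else table.dropna(subset=[trait])
    envs_per_g = df.groupby("genotype", observed=True)["environment"].nunique()
    t = stats.hmean(envs_per_g.to_numpy(dtype=float))
    reps_per_cell = df.groupby(["genotype", "environment"], observed=True).size()
    r = stats.hmean(reps_per_cell.to_numpy(dtype=float))
    return float(t), float(r)


def repeatability(var_G: float, var_GxE: float, var_R: float,
                  t: float, r: float, per_env: bool = False) -> float:
    """Repeatability from variance components.

    Entry-mean basis: sigma2_G / (sigma2_G + sigma2_GxE/t + sigma2_R/(r*t));
    per environment: sigma2_G / (sigma2_G + sigma2_R/r).
    """
    if t <= 0 or r <= 0:
        raise ValueError("t and r must be positive")
    var_G = float(var_G)
    var_R = float(var_R)
    if per_env:
        denom = var_G + var_R / r
    else:
        var_GxE = 0.0 if np.isnan(var_GxE) else float(var_GxE)
        denom = var_G + var_GxE / t + var_R / (r * t)
    if denom == 0:
        raise ValueError("repeatability undefined: all components zero")
    return var_G / denom


def repeatability_analysis(table: pd.DataFrame, trait: str,
                           anova: bool = True) -> RepeatabilityResult:
    """Variance components plus overall and per-environment repeatability."""
    comp = estimate_variance_components(table, trait, anova=anova)
    t, r = harmonic_design_means(table, trait)
    R_overall = repeatability(comp.var_G, comp.var_GxE, comp.var_R, t, r)
    per_env = {}
    for env, sub in table.dropna(subset=[trait]).groupby("environment",
                                                         observed=True):
        if sub["genotype"].nunique() < 2:
            continue
        c_env = estimate_variance_components(sub, trait, anova=False)
        _, r_env = harmonic_design_means(sub, trait)
        try:
            per_env[env] = repeatability(
                c_env.var_G, float("nan"), c_env.var_R, 1.0, r_env,
                per_env=True)
        except ValueError:
            per_env[env] = float("nan")
    return RepeatabilityResult(comp, t, r, R_overall, per_env)


# ---------------------------------------------------------------- QTL utils

def pve_from_lod(lod: float, n: int) -> float:
    """Percent phenotypic variance explained by a QTL with the given LOD
    score in a population of n individuals: 100 * (1 - 10^(-2*LOD/n))."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if lod < 0:
        raise ValueError("LOD must be >= 0")
    return 100.0 * (1.0 - 10.0 ** (-2.0 * lod / n))


_MARKER_RE = re.compile(r"^S(\d+)_(\d+)$")


def parse_marker(name: str) -> tuple[int, int]:
    """Parse a marker name S{chromosome}_{bp} into (chromosome, position)."""
    m = _MARKER_RE.match(str(name).strip())
    if not m:
        raise ValueError(f"unparseable marker name: {name!r}")
    chrom, pos = int(m.group(1)), int(m.group(2))
    if pos <= 0:
        raise ValueError(f"marker position must be positive: {name!r}")
    return chrom, pos


def lod_interval_width_mb(left_marker: str, right_marker: str) -> float:
    """Physical width (Mb, 2 decimals) of a QTL support interval from its
    flanking markers; both must sit on the same chromosome."""
    lc, lp = parse_marker(left_marker)
    rc, rp = parse_marker(right_marker)
    if lc != rc:
        raise ValueError(f"chromosome mismatch: {left_marker} vs {right_marker}")
    if rp < lp:
        raise ValueError("right marker precedes left marker")
    return round((rp - lp) / 1e6, 2)


def load_qtl_table(path=None) -> pd.DataFrame:
    """Load a QTL table (qtl_name, chromosome, closest_marker, lod,
    left_marker, right_marker, n_individuals).  With no path, returns the
    bundled carrot F2 shoot/root QTL table."""
    if path is None:
        from importlib.resources import files
        path = files("carrotmorph") / "data" / "qtl_f2.csv"
        with path.open() as fh:
            return pd.read_csv(fh)
    return pd.read_csv(path)


def qtl_support_table(table: pd.DataFrame, n_individuals: int | None = None
                      ) -> pd.DataFrame:
    """Add computed PVE and 1.5-LOD interval width columns to a QTL table.

    Expects columns qtl_name, chromosome, closest_marker, lod, left_marker,
    right_marker (and n_individuals unless passed explicitly).
    """
    out = table.copy()
    if n_individuals is None:
        if "n_individuals" not in out.columns:
            raise ValueError("n_individuals column or argument required")
        n_col = out["n_individuals"].astype(int)
    else:
        n_col = pd.Series(int(n_individuals), index=out.index)
    out["pve"] = [
        round(pve_from_lod(lod, n), 2)
        for lod, n in zip(out["lod"].astype(float), n_col)
    ]
    out["interval_mb"] = [
        lod_interval_width_mb(l, r)
        for l, r in zip(out["left_marker"], out["right_marker"])
    ]
    return out
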