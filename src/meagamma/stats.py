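"""Region-pair mixed-effects models of coherence and the nonparametric battery.

The model family mirrors the experimental design: response regressed on the
region-pair factor (within_CA3 reference) plus optional binary group
predictors, with random intercepts for slice and for the first electrode
of each pair nested in slice, fit by maximum likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .coherence import BETWEEN, WITHIN_CA1, WITHIN_CA3
from .errors import ModelError, ParameterError

REGION_LEVELS = (WITHIN_CA3, WITHIN_CA1, BETWEEN)


@dataclass
class LmeSpec:
    """Fixed-effect structure; the random structure is fixed (slice + nested elec1)."""

    fixed: tuple = ("Regions",)
    interaction: bool = False
    response: str = "fold_change"     # or "band_coherence"
    reference: str = WITHIN_CA3

    def formula(self) -> str:
        terms = []
        extra = [t for t in self.fixed if t != "Regions"]
        region_term = f"C(region_pair, Treatment('{self.reference}'))"
        if "Regions" in self.fixed:
            if extra and self.interaction:
                terms += [f"{t} * {region_term}" for t in extra]
            else:
                terms += extra + [region_term]
        else:
            terms += extra
        return f"{self.response} ~ 1 + " + " + ".join(terms) if terms else f"{self.response} ~ 1"


@dataclass
class LmeResult:
    fixed_effects: pd.DataFrame       # name, estimate, se, tstat, df, pvalue, ci_lo, ci_hi
    random_effects: pd.DataFrame      # group, sd, ci_lo, ci_hi
    loglik: float
    deviance: float
    aic: float
    bic: float
    n_obs: int
    n_groups: dict = field(default_factory=dict)
    converged: bool = True


def _pretty_fixed_names(names) -> list[str]:
    out = []
    for n in names:
        n = n.replace("C(region_pair, Treatment('within_CA3'))", "Regions")
        n = n.replace("[T.within_CA1]", "_CA1").replace("[T.between_CA1_CA3]", "_between")
        out.append(n)
    return out


def fit_lme(records: pd.DataFrame, spec: LmeSpec | None = None) -> LmeResult:
    """ML fit of response ~ fixed + (1 | Slice) + (1 | Slice:Elec1).

    Wald t statistics use residual degrees of freedom (n_obs - n_fixed).
    Random-effect SD intervals are Wald on the log-SD scale (residual SD
    via the chi-square interval); both are approximations.
    """
    spec = spec or LmeSpec()
    df = records.copy()
    needed = {"slice_id", "elec1", "region_pair", spec.response}
    missing = needed - set(df.columns)
    if missing:
        raise ParameterError(f"records missing columns: {sorted(missing)}")
    df = df.dropna(subset=[spec.response])
    if df["slice_id"].nunique() < 2:
        raise ModelError("need >= 2 slices to estimate the slice random effect")
    df["region_pair"] = pd.Categorical(df["region_pair"], categories=list(REGION_LEVELS))
    df["_elec1_key"] = df["slice_id"].astype(str) + ":" + df["elec1"].astype(str)

    formula = spec.formula()
    # pre-check the fixed design for rank deficiency, naming the aliased column
    from patsy import dmatrix
    rhs = formula.split("~", 1)[1]
    x = dmatrix(rhs, df, return_type="dataframe")
    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < x.shape[1]:
        for j in range(1, x.shape[1] + 1):
            if np.linalg.matrix_rank(x.to_numpy()[:, :j]) < j:
                raise ModelError(f"rank-deficient fixed design: column "
                                 f"{_pretty_fixed_names([x.columns[j - 1]])[0]!r} is aliased")
    for col in x.columns:
        if col != "Intercept" and x[col].nunique() < 2:
            raise ModelError(f"predictor {col!r} has a single observed level")

    model = sm.MixedLM.from_formula(
        formula, data=df, groups="slice_id", re_formula="1",
        vc_formula={"elec1": "0 + C(_elec1_key)"},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=False, method="lbfgs", maxiter=500)
        if not getattr(res, "converged", True):
            res = model.fit(reml=False, method="cg", maxiter=1000)

    k_fe = res.k_fe
    n = int(res.nobs)
    dof = n - k_fe
    est = np.asarray(res.fe_params)
    se = np.asarray(res.bse_fe)
    tstat = est / se
    pval = 2.0 * sps.t.sf(np.abs(tstat), dof)
    tcrit = sps.t.ppf(0.975, dof)
    fe = pd.DataFrame({
        "name": _pretty_fixed_names(res.fe_params.index),
        "estimate": est, "se": se, "tstat": tstat, "df": dof, "pvalue": pval,
        "ci_lo": est - tcrit * se, "ci_hi": est + tcrit * se,
    })

    scale = float(res.scale)
    var_slice = float(np.asarray(res.cov_re)[0, 0])
    var_elec = float(res.vcomp[0]) if len(res.vcomp) else 0.0
    sd_slice, sd_elec, sd_res = np.sqrt([var_slice, var_elec, scale])

    # Wald CIs on log-SD; statsmodels' bse for cov params are on the
    # scale-profiled parameterization, so multiply back by the scale.
    bse_all = np.asarray(res.bse)
    se_var_slice = bse_all[k_fe] * scale if bse_all.size > k_fe else np.nan
    se_var_elec = bse_all[k_fe + 1] * scale if bse_all.size > k_fe + 1 else np.nan

    def logsd_ci(sd_val: float, se_var: float) -> tuple[float, float]:
        if not np.isfinite(se_var) or sd_val <= 0:
            return (np.nan, np.nan)
        se_log_sd = se_var / (2.0 * sd_val ** 2)
        if se_log_sd > 50:  # variance indistinguishable from zero
            return (np.nan, np.nan)
        return (sd_val * np.exp(-1.96 * se_log_sd), sd_val * np.exp(1.96 * se_log_sd))

    lo_s, hi_s = logsd_ci(sd_slice, se_var_slice)
    lo_e, hi_e = logsd_ci(sd_elec, se_var_elec)
    chi_lo, chi_hi = sps.chi2.ppf([0.975, 0.025], dof)
    re = pd.DataFrame({
        "group": ["Slice", "Slice:Elec1", "Residual"],
        "sd": [sd_slice, sd_elec, sd_res],
        "ci_lo": [lo_s, lo_e, np.sqrt(scale * dof / chi_lo)],
        "ci_hi": [hi_s, hi_e, np.sqrt(scale * dof / chi_hi)],
    })

    loglik = float(res.llf)
    n_par = k_fe + 3  # two random-intercept variances + residual variance
    deviance = -2.0 * loglik
    return LmeResult(
        fixed_effects=fe, random_effects=re, loglik=loglik, deviance=deviance,
        aic=deviance + 2 * n_par, bic=deviance + np.log(n) * n_par, n_obs=n,
        n_groups={"Slice": int(df["slice_id"].nunique()),
                  "Slice:Elec1": int(df["_elec1_key"].nunique())},
        converged=bool(getattr(res, "converged", True)),
    )


def simulate_coherence_records(n_slices: int = 11, n_ca1: int = 12, n_ca3: int = 13,
                               intercept: float = 1.231, effect_ca1: float = 0.031,
                               effect_between: float = -0.104, sd_slice: float = 0.171,
                               sd_elec: float = 0.141, sd_resid: float = 0.175,
                               effect_group: float = 0.0, interaction_between: float = 0.0,
                               interaction_ca1: float = 0.0, group_col: str | None = None,
                               n_group_slices: int = 0, rng=None) -> pd.DataFrame:
    """Nested-variance generator for mixed-model recovery studies.

    Builds all electrode pairs per slice (region-pair label from electrode
    labels) and draws response = fixed structure + slice intercept + elec1
    intercept + noise.  When ``group_col`` is given, the last
    ``n_group_slices`` slices form the indicator group, with main effect and
    region interactions as configured.  Defaults reproduce the structure of
    the intact-circuit model estimates.
    """
    rng = np.random.default_rng(rng)
    rows = []
    for s in range(n_slices):
        in_group = group_col is not None and s >= n_slices - n_group_slices
        u_slice = rng.normal(0.0, sd_slice)
        regions = ["CA1"] * n_ca1 + ["CA3"] * n_ca3
        eids = np.arange(len(regions))
        u_elec = {int(e): rng.normal(0.0, sd_elec) for e in eids}
        for i in range(len(eids)):
            for j in range(i + 1, len(eids)):
                r1, r2 = regions[i], regions[j]
                if r1 == r2 == "CA1":
                    label, eff, ieff = WITHIN_CA1, effect_ca1, interaction_ca1
                elif r1 == r2 == "CA3":
                    label, eff, ieff = WITHIN_CA3, 0.0, 0.0
                else:
                    label, eff, ieff = BETWEEN, effect_between, interaction_between
                mu = intercept + eff + u_slice + u_elec[i]
                if in_group:
                    mu += effect_group + ieff
                rows.append({
                    "slice_id": f"s{s}", "elec1": int(i), "elec2": int(j),
                    "region_pair": label, "condition": "kainate",
                    "fold_change": mu + rng.normal(0.0, sd_resid),
                })
    df = pd.DataFrame.from_records(rows)
    df["band_coherence"] = df["fold_change"]
    if group_col is not None:
        group_slices = {f"s{s}" for s in range(n_slices - n_group_slices, n_slices)}
        df[group_col] = df["slice_id"].isin(group_slices).astype(int)
    return df


# ---------------------------------------------------------------------------
# nonparametric battery

def dunn_test(groups: dict[str, np.ndarray], p_adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's rank-based multiple comparisons after Kruskal-Wallis.

    Uses the tie-corrected normal approximation; p values are two-sided and
    Bonferroni-adjusted by default.
    """
    names = list(groups)
    values = [np.asarray(groups[g], float) for g in names]
    all_v = np.concatenate(values)
    n_total = all_v.size
    ranks = sps.rankdata(all_v)
    mean_ranks, sizes = [], []
    pos = 0
    for v in values:
        mean_ranks.append(ranks[pos:pos + v.size].mean())
        sizes.append(v.size)
        pos += v.size
    _, tie_counts = np.unique(all_v, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p = 2.0 * sps.norm.sf(abs(z))
            if p_adjust == "bonferroni":
                p = min(1.0, p * m)
            rows.append({"comparison": f"{names[i]} vs {names[j]}", "test": "dunn",
                         "statistic": z, "pvalue": p})
    return pd.DataFrame.from_records(rows)


def nonparametric_battery(groups: dict[str, np.ndarray], design: str) -> pd.DataFrame:
    """Dispatch the standard nonparametric tests.

    design = "paired": Wilcoxon signed-rank on two equal-length groups.
    design = "unpaired": Kolmogorov-Smirnov for 2 groups, Kruskal-Wallis
    followed by Dunn's comparisons for >= 3 groups.
    """
    names = list(groups)
    values = [np.asarray(groups[g], float) for g in names]
    for g, v in zip(names, values):
        if v.size == 0:
            raise ParameterError(f"group {g!r} is empty")
        if v.size < 3:
            raise ParameterError(f"group {g!r} has fewer than 3 values")
    rows = []
    if design == "paired":
        if len(values) != 2 or values[0].size != values[1].size:
            raise ParameterError("paired design needs two equal-length groups")
        diffs = values[0] - values[1]
        if np.all(diffs == 0):
            rows.append({"comparison": f"{names[0]} vs {names[1]}", "test": "wilcoxon",
                         "statistic": 0.0, "pvalue": 1.0, "note": "degenerate: all pairs tied"})
        else:
            st = sps.wilcoxon(values[0], values[1])
            rows.append({"comparison": f"{names[0]} vs {names[1]}", "test": "wilcoxon",
                         "statistic": float(st.statistic), "pvalue": float(st.pvalue),
                         "note": ""})
    elif design == "unpaired":
        if len(values) == 2:
            st = sps.ks_2samp(values[0], values[1])
            rows.append({"comparison": f"{names[0]} vs {names[1]}", "test": "ks",
                         "statistic": float(st.statistic), "pvalue": float(st.pvalue),
                         "note": ""})
        else:
            st = sps.kruskal(*values)
            rows.append({"comparison": "omnibus", "test": "kruskal-wallis",
                         "statistic": float(st.statistic), "pvalue": float(st.pvalue),
                         "note": ""})
            dunn = dunn_test(groups)
            dunn["note"] = ""
            rows.extend(dunn.to_dict("records"))
    else:
        raise ParameterError(f"unknown design {design!r}")
    return pd.DataFrame.from_records(rows)


def mad_outlier_mask(values: np.ndarray, n_mads: float = 5.0) -> np.ndarray:
    """Optional simple exclusion rule: True marks values beyond median +/- n_mads * MAD."""
    v = np.asarray(values, float)
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    if mad == 0:
        return np.zeros(v.size, bool)
    return np.abs(v - med) > n_mads * mad


def model_report(result: LmeResult) -> str:
    """Markdown report mirroring the published table layout."""
    lines = ["Linear mixed-effects model fit by ML", "",
             "## Model information", "",
             f"- Number of observations: {result.n_obs}",
             f"- Fixed effects coefficients: {len(result.fixed_effects)}",
             f"- Groups: " + ", ".join(f"{k}={v}" for k, v in result.n_groups.items()), "",
             "## Model fit statistics", "",
             "| AIC | BIC | LogLikelihood | Deviance |", "|---|---|---|---|",
             f"| {result.aic:.4g} | {result.bic:.4g} | {result.loglik:.4g} | "
             f"{result.deviance:.4g} |", "",
             "## Fixed effects coefficients (95% CIs)", "",
             "| Name | Estimate | SE | t stat | df | p value | Lower | Upper |",
             "|---|---|---|---|---|---|---|---|"]
    for _, r in result.fixed_effects.iterrows():
        lines.append(f"| {r['name']} | {r['estimate']:.4g} | {r['se']:.4g} | "
                     f"{r['tstat']:.4g} | {int(r['df'])} | {r['pvalue']:.4g} | "
                     f"{r['ci_lo']:.4g} | {r['ci_hi']:.4g} |")
    lines += ["", "## Random effects (SDs, 95% CIs)", "",
              "| Group | Std | Lower | Upper |", "|---|---|---|---|"]
    for _, r in result.random_effects.iterrows():
        lines.append(f"| {r['group']} | {r['sd']:.4g} | {r['ci_lo']:.4g} | {r['ci_hi']:.4g} |")
    return "\n".join(lines) + "\n"
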