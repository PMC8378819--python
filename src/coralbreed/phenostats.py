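"""Survival-rate statistics for a dam x sire larval breeding experiment.

Covers standardisation of heat survival to ambient values, origin and
parental-identity linear models with partial eta-squared effect sizes,
per-family decline tests with FDR correction, the paternal survival index
(h/m - 1), narrow-sense heritability via a Gibbs-sampled sire-dam variance
component model, and field juvenile survival summaries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.multicomp import pairwise_tukeyhsd

log = logging.getLogger(__name__)

AMBIENT = 27.0


def survival_rates(table: pd.DataFrame) -> pd.DataFrame:
    """Raw survival rate per row: n_alive_60h / n_start."""
    out = table.copy()
    out["survival"] = out["n_alive_60h"] / out["n_start"]
    return out


def relative_survival(table: pd.DataFrame, ambient: float = AMBIENT) -> pd.DataFrame:
    """Standardise survival at elevated temperatures to each family's ambient value.

    The divisor is the family's mean ambient survival (across plates, when a
    plate column is present), which accounts for mortality unrelated to heat.
    Values are capped at 1.0; families with zero ambient survival are set to
    missing with a warning.  Rows at the ambient temperature are dropped.
    """
    df = survival_rates(table)
    amb = (df[df["temperature"] == ambient]
           .groupby("family_id")["survival"].mean())
    heat = df[df["temperature"] != ambient].copy()
    missing_amb = set(heat["family_id"]) - set(amb.index)
    if missing_amb:
        raise ValueError(f"families lack an ambient row: {sorted(missing_amb)}")
    denom = heat["family_id"].map(amb)
    zero = denom == 0
    if zero.any():
        log.warning("%d families have zero ambient survival; standardised "
                    "values set to missing", heat.loc[zero, "family_id"].nunique())
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(zero, np.nan, heat["survival"] / denom)
    heat["relative_survival"] = np.minimum(rel, 1.0)
    return heat


@dataclass
class OriginEffectResult:
    anova: pd.DataFrame                 # Type-II ANOVA of the cubed response
    tukey: pd.DataFrame                 # pairwise origin comparisons per temperature
    means: pd.DataFrame                 # raw-scale origin x temperature means
    single_origin: bool = False


def origin_effect_model(rel_table: pd.DataFrame) -> OriginEffectResult:
    """Two-way model of relative survival on temperature and parental origin.

    The response is cubed before fitting to improve normality and variance
    homogeneity, then analysed as response ~ temperature * origin with
    Tukey honest-significant-difference origin comparisons within each
    temperature.  Raw-scale means accompany the transformed-scale tests.
    """
    df = rel_table.dropna(subset=["relative_survival"]).copy()
    df["resp"] = df["relative_survival"] ** 3
    df["temperature"] = df["temperature"].astype(float)
    origins = df["origin"].unique()
    single = len(origins) < 2
    if single:
        log.warning("single origin level; model degenerates to temperature only")
        formula = "resp ~ C(temperature)"
    else:
        formula = "resp ~ C(temperature) * C(origin)"
    fit = smf.ols(formula, data=df).fit()
    anova = sm.stats.anova_lm(fit, typ=2)

    tukey_rows = []
    if not single:
        for temp, grp in df.groupby("temperature"):
            if grp["origin"].nunique() < 2:
                continue
            res = pairwise_tukeyhsd(grp["resp"], grp["origin"])
            frame = pd.DataFrame(
                res.summary().data[1:], columns=res.summary().data[0])
            frame.insert(0, "temperature", temp)
            tukey_rows.append(frame)
    tukey = (pd.concat(tukey_rows, ignore_index=True)
             if tukey_rows else pd.DataFrame())
    means = (df.groupby(["origin", "temperature"])["relative_survival"]
             .agg(["mean", "sem", "count"]).reset_index())
    return OriginEffectResult(anova=anova, tukey=tukey, means=means,
                              single_origin=single)


def family_decline_tests(
    rel_table: pd.DataFrame, temperature: float = 36.0,
) -> pd.DataFrame:
    """Per-family one-tailed test of standardised survival < 1 at 36 degC.

    Uses plate-level replicate values; p-values are Benjamini-Hochberg
    adjusted across families.  Zero-variance replicate sets get the exact
    decision (all below 1: p ~ 0; all at 1: p = 1) with a warning.
    """
    df = rel_table[rel_table["temperature"] == temperature].dropna(
        subset=["relative_survival"])
    rows = []
    for fam, grp in df.groupby("family_id"):
        vals = grp["relative_survival"].to_numpy()
        if len(vals) < 2:
            raise ValueError(f"family {fam}: need >=2 replicate values")
        if np.ptp(vals) == 0.0:
            log.warning("family %s: zero-variance replicates", fam)
            p = 0.0 if vals[0] < 1.0 else 1.0
        else:
            p = stats.ttest_1samp(vals, 1.0, alternative="less").pvalue
        rows.append({"family_id": fam, "mean_relative_survival": vals.mean(),
                     "n_replicates": len(vals), "p": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant_decline"] = out["p_adj"] < 0.05
    return out


def variance_explained(
    rel_table: pd.DataFrame,
    factors: list[str],
    response: str = "relative_survival",
) -> pd.DataFrame:
    """Partial eta-squared per factor from a linear model on the factors.

    eta_p^2 = SS_effect / (SS_effect + SS_residual), with Type-II sums of
    squares for multi-factor (e.g. mother + father) models, which are not
    balanced in a realised cross design.
    """
    df = rel_table.dropna(subset=[response]).copy()
    df["_y"] = df[response]
    terms = " + ".join(f"C({f})" for f in factors)
    fit = smf.ols(f"_y ~ {terms}", data=df).fit()
    if fit.df_resid <= 0:
        raise ValueError(
            f"saturated model: no residual degrees of freedom with factors {factors}")
    anova = sm.stats.anova_lm(fit, typ=2)
    ss_resid = anova.loc["Residual", "sum_sq"]
    rows = []
    for f in factors:
        ss = anova.loc[f"C({f})", "sum_sq"]
        rows.append({
            "factor": f,
            "eta_p_squared": ss / (ss + ss_resid),
            "p": anova.loc[f"C({f})", "PR(>F)"],
        })
    return pd.DataFrame(rows)


def survival_index(
    table: pd.DataFrame, temperature: float = 36.0,
    value_col: str | None = None,
) -> pd.DataFrame:
    """Survival index (h/m - 1): family heat survival relative to its maternal mean.

    ``h`` is the family's survival at 36 degC and ``m`` the mean over all
    families sharing the dam, which isolates the paternal contribution.
    Returns one row per family plus the per-sire mean index.
    """
    if value_col is None:
        df = survival_rates(table)
        value_col = "survival"
    else:
        df = table.copy()
    df = df[df["temperature"] == temperature]
    fam = (df.groupby(["family_id", "dam_id", "sire_id"])[value_col]
           .mean().rename("h").reset_index())
    maternal = fam.groupby("dam_id")["h"].mean().rename("m")
    fam = fam.merge(maternal, on="dam_id")
    zero = fam["m"] == 0
    if zero.any():
        log.warning("%d dams have zero maternal mean; index set to missing",
                    fam.loc[zero, "dam_id"].nunique())
    with np.errstate(divide="ignore", invalid="ignore"):
        fam["index"] = np.where(zero, np.nan, fam["h"] / fam["m"] - 1.0)
    return fam[["sire_id", "dam_id", "family_id", "h", "m", "index"]]


def sire_mean_index(index_table: pd.DataFrame) -> pd.Series:
    """Mean survival index per sire (paternal performance)."""
    return index_table.groupby("sire_id")["index"].mean()


# ---------------------------------------------------------------------------
# Heritability: Gibbs sampler for the sire-dam Gaussian variance-component model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChainConfig:
    """MCMC settings; the default chain is a shortened desk-scale run.

    The original-scale analysis settings (1e6 iterations, 1e5 burn-in,
    thinning 100) are available as :meth:`full_scale`.
    """

    iterations: int = 100_000
    burn_in: int = 10_000
    thin: int = 10
    nu: float = 0.002    # weakly informative inverse-gamma prior df
    V: float = 1.0       # prior scale

    @classmethod
    def full_scale(cls) -> "ChainConfig":
        return cls(iterations=1_000_000, burn_in=100_000, thin=100)


@dataclass
class HeritabilityEstimate:
    """Posterior samples and summaries of the variance components.

    ``h2_narrow`` uses h2 = V_A / (V_A + V_R) and ``h2_maternal`` uses
    h2 = V_A / (V_A + V_M + V_R), with V_A = 4 V_sire (paternal half-sib
    identity), V_M = V_dam and V_R the residual variance.
    """

    samples: pd.DataFrame        # columns V_sire, V_dam, V_resid, V_A, h2_*
    config: ChainConfig
    seed: int
    formula: str = "y ~ 1 + sire + dam (random)"
    ess: float = float("nan")

    def summary(self) -> pd.DataFrame:
        rows = []
        for col in self.samples.columns:
            s = self.samples[col].to_numpy()
            lo, hi = np.percentile(s, [2.5, 97.5])
            rows.append({"parameter": col, "mean": s.mean(),
                         "ci95_low": lo, "ci95_high": hi})
        return pd.DataFrame(rows)


def _effective_sample_size(x: np.ndarray) -> float:
    """Initial-positive-sequence autocorrelation ESS estimate."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 10 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1) * x.var())
    s = 0.0
    for k in range(1, n):
        if acf[k] <= 0:
            break
        s += acf[k]
    return float(n / (1.0 + 2.0 * s))


def estimate_heritability(
    data: pd.DataFrame,
    chain: ChainConfig | None = None,
    seed: int = 0,
    response: str = "relative_survival",
) -> HeritabilityEstimate:
    """Gibbs sampler for y = mu + sire + dam + e with inverse-gamma priors.

    ``data`` must contain sire_id, dam_id and the response column, with at
    least two distinct sires and two distinct dams.  All three variance
    components get scaled-inverse-chi-squared (nu, V) priors; the posterior
    is sampled by full conditional updates.  A low effective sample size of
    h2 (< 100) triggers a warning, not a failure.
    """
    if chain is None:
        chain = ChainConfig()
    df = data.dropna(subset=[response])
    y = df[response].to_numpy(dtype=float)
    sire_idx, sires = pd.factorize(df["sire_id"], sort=True)
    dam_idx, dams = pd.factorize(df["dam_id"], sort=True)
    n_s, n_d, n = len(sires), len(dams), len(y)
    if n_s < 2 or n_d < 2:
        raise ValueError("need >=2 sires and >=2 dams for the variance model")

    rng = np.random.default_rng(seed)
    nu, V = chain.nu, chain.V
    s_eff = np.zeros(n_s)
    d_eff = np.zeros(n_d)
    mu = y.mean()
    vs = vd = ve = max(y.var(), 1e-6)
    n_per_s = np.bincount(sire_idx, minlength=n_s)
    n_per_d = np.bincount(dam_idx, minlength=n_d)

    kept = []
    for it in range(chain.iterations):
        # sire effects
        resid = y - mu - d_eff[dam_idx]
        sums = np.bincount(sire_idx, weights=resid, minlength=n_s)
        prec = n_per_s / ve + 1.0 / vs
        mean = (sums / ve) / prec
        s_eff = mean + rng.standard_normal(n_s) / np.sqrt(prec)
        # dam effects
        resid = y - mu - s_eff[sire_idx]
        sums = np.bincount(dam_idx, weights=resid, minlength=n_d)
        prec = n_per_d / ve + 1.0 / vd
        mean = (sums / ve) / prec
        d_eff = mean + rng.standard_normal(n_d) / np.sqrt(prec)
        # grand mean (flat prior)
        resid = y - s_eff[sire_idx] - d_eff[dam_idx]
        mu = resid.mean() + rng.standard_normal() * np.sqrt(ve / n)
        # variance components: scaled-inv-chi2(nu + q, (nu V + SS)/(nu + q))
        e = resid - mu
        vs = (nu * V + (s_eff ** 2).sum()) / rng.chisquare(nu + n_s)
        vd = (nu * V + (d_eff ** 2).sum()) / rng.chisquare(nu + n_d)
        ve = (nu * V + (e ** 2).sum()) / rng.chisquare(nu + n)
        if it >= chain.burn_in and (it - chain.burn_in) % chain.thin == 0:
            kept.append((vs, vd, ve))

    arr = np.array(kept)
    samples = pd.DataFrame(arr, columns=["V_sire", "V_dam", "V_resid"])
    samples["V_A"] = 4.0 * samples["V_sire"]
    samples["V_M"] = samples["V_dam"]
    samples["h2_narrow"] = samples["V_A"] / (samples["V_A"] + samples["V_resid"])
    samples["h2_maternal"] = samples["V_A"] / (
        samples["V_A"] + samples["V_M"] + samples["V_resid"])
    ess = _effective_sample_size(samples["h2_maternal"].to_numpy())
    if ess < 100:
        warnings.warn(f"low effective sample size for h2 ({ess:.0f} < 100); "
                      "consider a longer chain", stacklevel=2)
    return HeritabilityEstimate(samples=samples, config=chain, seed=seed, ess=ess)


def field_survival_summary(field_table: pd.DataFrame) -> pd.DataFrame:
    """Per-origin juvenile field survival: rates, survivor-family fractions, ratio.

    ``field_table`` has one row per family with columns family_id, origin,
    n_deployed, n_survivors.  The summary reports survivors/deployed per
    origin, the fraction of families with at least one survivor, and the
    hybrid:PG rate ratio (missing when undefined).
    """
    df = field_table.copy()
    zero = df.groupby("origin")["n_deployed"].sum() == 0
    if zero.any():
        omitted = list(zero.index[zero])
        log.warning("origins with zero deployed omitted: %s", omitted)
        df = df[~df["origin"].isin(omitted)]
    g = df.groupby("origin")
    out = pd.DataFrame({
        "n_deployed": g["n_deployed"].sum(),
        "n_survivors": g["n_survivors"].sum(),
        "n_families": g.size(),
        "families_with_survivors": g.apply(
            lambda x: (x["n_survivors"] > 0).mean(), include_groups=False),
    })
    out["rate"] = out["n_survivors"] / out["n_deployed"]
    ratio = np.nan
    if "PGxIO" in out.index and "PG" in out.index and out.loc["PG", "rate"] > 0:
        ratio = out.loc["PGxIO", "rate"] / out.loc["PG", "rate"]
    out.attrs["hybrid_pg_ratio"] = float(ratio)
    return out
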