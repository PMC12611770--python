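"""Association of clonal-landscape summaries with donor covariates.

Responses (per-sample mutation densities, per-sample dN/dS on the log
scale, activating promoter-mutation density) are regressed on donor
covariates with linear mixed-effects models carrying a donor-level random
intercept, so paired samples (dome and trigone of one bladder) do not
count as independent observations.  A two-step screen — univariate models
first, multivariate confirmation second — feeds Benjamini–Hochberg FDR
control within each response family; associations with q < 0.2 are called
significant.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

FDR_THRESHOLD = 0.2
SCREEN_ALPHA = 0.05  # univariate screening level before multivariate confirmation
LOG_OFFSET = 0.5     # offset inside log(dN/dS + offset) responses

DEFAULT_TERMS = ("age_decades", "sexM", "smoking_ever", "alcohol", "bmi_scaled", "chemo")


def build_design(covariates: pd.DataFrame,
                 terms=DEFAULT_TERMS,
                 interaction: bool = False) -> pd.DataFrame:
    """Numeric fixed-effects design from the covariate table.

    Sex is coded male=1, smoking ever=1; samples from donors with unknown
    smoking history are dropped from any design touching smoking.  With
    ``interaction`` the age and smoking main effects are replaced by their
    product (used for activating promoter-mutation density).
    """
    cov = covariates.copy()
    cov["sexM"] = (cov["sex"] == "M").astype(float)
    needs_smoking = interaction or any("smoking" in t for t in terms)
    if needs_smoking:
        cov = cov[cov["smoking"] != "unknown"]
    cov["smoking_ever"] = (cov["smoking"] == "ever").astype(float)
    for col in ("alcohol", "chemo"):
        if col in cov:
            cov[col] = cov[col].astype(float)
    design = cov.set_index("sample_id")
    cols = list(terms)
    if interaction:
        design["age_x_smoking"] = design["age_decades"] * design["smoking_ever"]
        cols = [c for c in cols if c not in ("age_decades", "smoking_ever")]
        cols.append("age_x_smoking")
    out = design[["donor_id"] + cols]
    return out


def _fit_mixed(y: np.ndarray, X: pd.DataFrame, groups: np.ndarray):
    """One random-intercept fit; returns None on a singular/non-converged fit."""
    exog = sm.add_constant(X, has_constant="add")
    for fit_kwargs in ({"reml": True},
                       {"reml": True, "method": "lbfgs", "maxiter": 200},
                       {"reml": True, "method": "powell", "maxiter": 50}):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM(y, exog, groups=groups)
                res = model.fit(**fit_kwargs)
            if (np.all(np.isfinite(res.fe_params))
                    and np.all(np.isfinite(res.bse_fe))):
                return res
        except (np.linalg.LinAlgError, ValueError):
            continue
    return None


def run_models(
    responses: pd.DataFrame,
    covariates: pd.DataFrame,
    terms=DEFAULT_TERMS,
    interaction_responses: tuple[str, ...] = (),
    fdr: float = FDR_THRESHOLD,
    screen_alpha: float = SCREEN_ALPHA,
    two_step: bool = True,
) -> pd.DataFrame:
    """Mixed-effects association of each response with donor covariates.

    Parameters
    ----------
    responses
        Sample-indexed frame, one column per response variable.
    covariates
        Per-sample covariate table (see :func:`selscope.catalog_io.load_covariates`).
    interaction_responses
        Response columns modeled with the age×smoking interaction instead
        of separate age and smoking terms.
    two_step
        Univariate screen (``screen_alpha``) before the multivariate model;
        terms failing the screen are reported but not FDR-ranked.

    Returns one row per (response, term) with the multivariate effect, its
    95% CI, univariate and multivariate p-values, BH q within the response
    family, and the q < ``fdr`` significance call.
    """
    rows = []
    for response in responses.columns:
        use_inter = response in interaction_responses
        design = build_design(covariates, terms, interaction=use_inter)
        merged = design.join(responses[response].rename("_y"), how="inner").dropna()
        if merged.empty:
            continue
        y = merged["_y"].to_numpy(dtype=float)
        groups = merged["donor_id"].to_numpy()
        fixed = merged.drop(columns=["donor_id", "_y"])
        n = len(merged)

        p_uni = {}
        for term in fixed.columns:
            res = _fit_mixed(y, fixed[[term]], groups)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p_uni[term] = (float(res.pvalues[term])
                               if res is not None else np.nan)

        multi = _fit_mixed(y, fixed, groups)
        for term in fixed.columns:
            if multi is not None:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    effect = float(multi.params[term])
                    se = float(multi.bse[term])
                    p_multi = float(multi.pvalues[term])
                ci = (effect - 1.96 * se, effect + 1.96 * se)
            else:
                effect, p_multi, ci = np.nan, np.nan, (np.nan, np.nan)
            screened = (not two_step) or (
                np.isfinite(p_uni[term]) and p_uni[term] < screen_alpha
            )
            rows.append({
                "response": response, "term": term, "effect": effect,
                "ci_low": ci[0], "ci_high": ci[1],
                "p_univariate": p_uni[term], "p_value": p_multi,
                "n_samples": n, "converged": multi is not None,
                "screened": bool(screened),
            })
    out = pd.DataFrame(rows)
    if out.empty:
        return out

    out["q_value"] = np.nan
    for response, grp in out.groupby("response"):
        mask = grp["screened"] & grp["converged"] & grp["p_value"].notna()
        idx = grp.index[mask]
        if len(idx):
            out.loc[idx, "q_value"] = multipletests(
                out.loc[idx, "p_value"], method="fdr_bh")[1]
    out["significant"] = out["q_value"] < fdr
    return out


def dnds_response_matrix(per_sample: pd.DataFrame,
                         log_offset: float = LOG_OFFSET,
                         eligible_only: bool = True) -> pd.DataFrame:
    """Pivot per-sample dN/dS into a sample × response matrix.

    Responses are ``log(dN/dS + offset)``: dN/dS is a positive ratio with
    multiplicative noise, and the offset keeps zero-count samples finite.
    Only (gene, class) combinations computable for ≥80% of samples enter.
    """
    df = per_sample
    if eligible_only:
        df = df[df["eligible"]]
    df = df[~df["missing"]].copy()
    df["response"] = "dnds_" + df["mclass"] + ":" + df["gene"]
    wide = df.pivot_table(index="sample_id", columns="response", values="dnds")
    return np.log(wide + log_offset)


def density_responses(mutations: pd.DataFrame, panel,
                      whitelist: set | None = None) -> pd.DataFrame:
    """Per-sample mutation densities (per Mb sequenced): protein-affecting,
    non-protein-affecting, and activating promoter mutations."""
    mb = panel.total_bp() / 1e6
    affecting = ("missense", "nonsense", "essential_splice",
                 "frameshift_indel", "inframe_indel")
    out = {}
    grouped = mutations.groupby("sample_id")
    for sample, grp in grouped:
        rec = {
            "density_protein_affecting":
                grp["consequence"].isin(affecting).sum() / mb,
            "density_non_protein_affecting":
                grp["consequence"].isin(["synonymous", "noncoding"]).sum() / mb,
        }
        if whitelist is not None:
            n_act = sum(
                (c, p, a) in whitelist
                for c, p, a in zip(grp["chrom"], grp["pos"], grp["alt"])
            )
            rec["density_activating_pTERT"] = n_act / mb
        out[sample] = rec
    return pd.DataFrame(out).T.rename_axis("sample_id")
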