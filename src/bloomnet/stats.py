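"""Experiment-level inference on per-network metrics.

The experimental design is a randomized block: one plot per treatment
(C, F, H, HF) in each of 8 blocks (site-years).  Treatment effects on each
network metric are tested with a Gaussian linear mixed model fitted by
REML: fixed effects are treatment (reference level C) and the log floral
display, with a random intercept per block.  A treatment x display
interaction is fitted first and dropped when no interaction contrast
reaches p < 0.05.  Model fit is summarized by Nakagawa's marginal R^2
(fixed effects only) and conditional R^2 (fixed + random).

The responses are modelled on the Gaussian scale (log-transformed where
abundance-like); this matches reporting of t statistics and log-scale
effect sizes rather than count-family link functions.

Per-species foraging breadth (number of plant species visited per plot) is
compared across treatments with a Kruskal-Wallis test plus Dunn-type
pairwise mean-rank contrasts against the control, Bonferroni-corrected
over the family of species tested.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

__all__ = [
    "ModelSpec",
    "EffectTable",
    "fit_lmm",
    "r2_nakagawa",
    "kruskal_pairwise",
    "correlation_matrix",
]

CONTRAST_ORDER = ("F", "H", "HF")


@dataclass
class ModelSpec:
    """Specification of one treatment-contrast mixed model."""

    response: str
    log_response: bool = False
    include_display: bool = True
    test_interaction: bool = True
    reference: str = "C"
    interaction_alpha: float = 0.05


@dataclass
class EffectTable:
    """Fixed-effect contrasts from one fitted mixed model."""

    response: str
    rows: pd.DataFrame        # columns: term, contrast, effect, t, p
    r2m: float
    r2c: float
    n_obs: int
    n_groups: int
    interaction_retained: bool
    converged: bool

    def contrast(self, name: str) -> pd.Series:
        """Look up one contrast row, e.g. ``"C-F"`` or ``"display"``."""
        hit = self.rows[self.rows["contrast"] == name]
        if hit.empty:
            raise KeyError(name)
        return hit.iloc[0]


def r2_nakagawa(
    var_fixed: float, var_random: float, var_resid: float
) -> tuple[float, float]:
    """Marginal and conditional R^2 from variance components.

    R2m = vf / (vf + va + ve); R2c = (vf + va) / (vf + va + ve).
    """
    if min(var_fixed, var_random, var_resid) < 0:
        raise ValueError("variance components must be non-negative")
    total = var_fixed + var_random + var_resid
    if total == 0:
        raise ValueError("all variance components are zero; R^2 undefined")
    return var_fixed / total, (var_fixed + var_random) / total


def _formula(spec: ModelSpec, with_interaction: bool) -> str:
    tr = f"C(treatment, Treatment('{spec.reference}'))"
    rhs = tr
    if spec.include_display:
        rhs = f"{tr} * __display" if with_interaction else f"{tr} + __display"
    return f"__y ~ {rhs}"


def _fit_one(data: pd.DataFrame, spec: ModelSpec, with_interaction: bool):
    model = smf.mixedlm(
        _formula(spec, with_interaction), data, groups=data["block"]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True)
    return res


def _term_rows(res, spec: ModelSpec, n_obs: int) -> pd.DataFrame:
    k = len(res.fe_params)
    df_resid = max(n_obs - k, 1)
    rows = []
    for term, beta in res.fe_params.items():
        if term == "Intercept":
            continue
        se = res.bse_fe[term]
        t = beta / se
        p = 2 * sps.t.sf(abs(t), df_resid)
        if "__display" in term and "Treatment" not in term:
            contrast = "display"
        elif ":" in term:
            level = term.split("[T.")[1].split("]")[0]
            contrast = f"{level}:display"
        elif "[T." in term:
            level = term.split("[T.")[1].split("]")[0]
            contrast = f"{spec.reference}-{level}"
        else:
            contrast = term
        rows.append(
            {"term": term, "contrast": contrast, "effect": float(beta),
             "t": float(t), "p": float(p)}
        )
    return pd.DataFrame(rows)


def fit_lmm(data: pd.DataFrame, spec: ModelSpec) -> EffectTable:
    """Fit the treatment-contrast mixed model for one response.

    ``data`` needs columns ``treatment``, ``block``, ``display_log`` (when
    the display covariate is used) and the response.  The treatment x
    display interaction is fitted first (when requested) and removed unless
    some interaction contrast has p below ``spec.interaction_alpha``.
    Singular random-effect fits are reported with ``converged=False``.
    """
    data = data.copy()
    y = data[spec.response].astype(float)
    if spec.log_response:
        if (y <= 0).any():
            raise ValueError(f"cannot log-transform non-positive {spec.response}")
        y = np.log(y)
    data["__y"] = y
    if not np.isfinite(data["__y"]).all():
        raise ValueError(f"non-finite response values in {spec.response}")
    if data["block"].nunique() < 2:
        raise ValueError("need at least 2 blocks")
    if spec.include_display:
        # mean-centered so treatment contrasts are evaluated at the average
        # floral display even when a treatment x display interaction is kept
        data["__display"] = data["display_log"] - data["display_log"].mean()

    n_obs = len(data)
    if float(np.std(data["__y"])) == 0.0:
        # a constant response carries no treatment or display signal
        contrasts = [f"{spec.reference}-{t}"
                     for t in sorted(data["treatment"].unique())
                     if t != spec.reference]
        if spec.include_display:
            contrasts.append("display")
        rows = pd.DataFrame(
            [{"term": c, "contrast": c, "effect": 0.0, "t": 0.0, "p": 1.0}
             for c in contrasts]
        )
        return EffectTable(
            response=spec.response, rows=rows, r2m=0.0, r2c=0.0,
            n_obs=n_obs, n_groups=data["block"].nunique(),
            interaction_retained=False, converged=True,
        )
    interaction_retained = False
    res = None
    if spec.test_interaction and spec.include_display:
        res_int = _fit_one(data, spec, with_interaction=True)
        rows_int = _term_rows(res_int, spec, n_obs)
        inter = rows_int[rows_int["contrast"].str.endswith(":display")]
        if (inter["p"] < spec.interaction_alpha).any():
            interaction_retained = True
            res = res_int
            rows = rows_int
    if res is None:
        res = _fit_one(data, spec, with_interaction=False)
        rows = _term_rows(res, spec, n_obs)

    exog = res.model.exog
    var_fixed = float(np.var(exog @ res.fe_params.to_numpy()))
    var_random = float(np.asarray(res.cov_re)[0, 0])
    var_resid = float(res.scale)
    r2m, r2c = r2_nakagawa(var_fixed, var_random, var_resid)
    return EffectTable(
        response=spec.response,
        rows=rows.reset_index(drop=True),
        r2m=r2m,
        r2c=r2c,
        n_obs=n_obs,
        n_groups=data["block"].nunique(),
        interaction_retained=interaction_retained,
        converged=bool(res.converged),
    )


def kruskal_pairwise(
    values: pd.Series | np.ndarray,
    groups: pd.Series | np.ndarray,
    reference: str = "C",
    bonferroni_m: int = 10,
) -> pd.DataFrame:
    """Kruskal-Wallis plus Dunn-type contrasts against the control.

    Returns one row per non-reference group with the mean rank difference
    (group minus reference), the tie-corrected normal-approximation z and
    two-sided p, and the Bonferroni-adjusted p (family size
    ``bonferroni_m``, the number of species tested).  Groups with zero
    observations come back with missing contrasts.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups).astype(str)
    present = [g for g in pd.unique(groups) if (groups == g).sum() > 0]
    if len(present) < 2:
        raise ValueError("need at least 2 groups with data")
    samples = [values[groups == g] for g in present]
    h_stat, h_p = sps.kruskal(*samples)

    n_total = len(values)
    ranks = sps.rankdata(values)
    mean_rank = {g: ranks[groups == g].mean() for g in present}
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    others = [g for g in present if g != reference] + [
        g for g in np.unique(groups) if g not in present
    ]
    for g in others:
        if g not in present or reference not in present:
            rows.append({"group": g, "mean_rank_diff": np.nan, "z": np.nan,
                         "p": np.nan, "p_bonferroni": np.nan})
            continue
        n1 = (groups == reference).sum()
        n2 = (groups == g).sum()
        diff = mean_rank[g] - mean_rank[reference]
        se = np.sqrt(var_base * (1.0 / n1 + 1.0 / n2))
        z = diff / se if se > 0 else np.nan
        p = 2 * sps.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append({
            "group": g, "mean_rank_diff": float(diff), "z": float(z),
            "p": float(p), "p_bonferroni": float(min(1.0, bonferroni_m * p)),
        })
    out = pd.DataFrame(rows)
    out.attrs["kruskal_H"] = float(h_stat)
    out.attrs["kruskal_p"] = float(h_p)
    return out


def correlation_matrix(
    table: pd.DataFrame, variables: list[str], alpha: float = 0.05
) -> pd.DataFrame:
    """Pairwise Pearson correlations with significance flags.

    Returns long-format rows (var1, var2, r, p, significant); pairs with a
    zero-variance member or fewer than 3 complete observations are reported
    missing.
    """
    rows = []
    for a, b in itertools.combinations(variables, 2):
        sub = table[[a, b]].dropna()
        if len(sub) < 3 or sub[a].std() == 0 or sub[b].std() == 0:
            rows.append({"var1": a, "var2": b, "r": np.nan, "p": np.nan,
                         "significant": False})
            continue
        r, p = sps.pearsonr(sub[a], sub[b])
        rows.append({"var1": a, "var2": b, "r": float(r), "p": float(p),
                     "significant": bool(p < alpha)})
    return pd.DataFrame(rows)
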