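"""Survival machinery: Kaplan–Meier, log-rank, univariate Cox.

Thin, validated wrappers around lifelines, plus the grouped comparisons
the clonal-architecture analysis needs: both/dominant-only/secondary-only/
neither carrier groups for a gene, VAF strata (cut at 0.4, low stratum
inclusive), and CH-class comparisons.  Ties in event times use the Efron
approximation (lifelines' default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

from clonehier.cohort_model import ValidationError


@dataclass
class SurvivalGroup:
    label: str
    patient_ids: list[str]
    times: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.events = np.asarray(self.events, bool)
        if len(self.times) == 0:
            raise ValidationError(f"group {self.label!r} has no subjects")
        if (self.times < 0).any():
            raise ValidationError(f"group {self.label!r} has negative times")


def group_from_clinical(clinical: pd.DataFrame, patient_ids, label: str) -> SurvivalGroup:
    sub = clinical[clinical["patient_id"].isin(set(patient_ids))]
    return SurvivalGroup(label=label, patient_ids=list(sub["patient_id"]),
                         times=sub["os_months"].to_numpy(float),
                         events=sub["os_event"].to_numpy(bool))


def km_estimate(group: SurvivalGroup) -> dict:
    """Product-limit estimate with Greenwood variance and median survival.

    Median = earliest time with S(t) ≤ 0.5; NaN when never reached.
    """
    kmf = KaplanMeierFitter()
    kmf.fit(group.times, group.events, label=group.label)
    table = kmf.event_table.copy()
    surv = kmf.survival_function_.iloc[:, 0]
    var = kmf._cumulative_sq_ if hasattr(kmf, "_cumulative_sq_") else None
    out = pd.DataFrame({
        "time": surv.index.to_numpy(float),
        "at_risk": table["at_risk"].to_numpy(float),
        "observed": table["observed"].to_numpy(float),
        "survival": surv.to_numpy(float),
    })
    # Greenwood variance of S(t)
    with np.errstate(divide="ignore", invalid="ignore"):
        d, r = out["observed"].to_numpy(), out["at_risk"].to_numpy()
        terms = np.where(r * (r - d) > 0, d / (r * (r - d)), 0.0)
        out["greenwood_var"] = out["survival"].to_numpy() ** 2 * np.cumsum(terms)
    reached = out[out["survival"] <= 0.5]
    median = float(reached["time"].iloc[0]) if len(reached) else float("nan")
    return {"table": out, "median": median, "fitter": kmf}


def logrank(groups: list[SurvivalGroup]) -> dict:
    """k-group log-rank test (df = k − 1)."""
    if len(groups) < 2:
        raise ValidationError("log-rank needs at least two groups")
    times = np.concatenate([g.times for g in groups])
    events = np.concatenate([g.events for g in groups])
    labels = np.concatenate([[g.label] * len(g.times) for g in groups])
    res = multivariate_logrank_test(times, labels, events)
    return {"statistic": float(res.test_statistic), "p": float(res.p_value),
            "df": len(groups) - 1}


def cox_hr(group_indicator, times, events) -> dict:
    """Univariate Cox hazard ratio with Wald 95% CI (Efron ties).

    ``group_indicator`` is a 0/1 vector; the HR contrasts 1 vs 0.  Returns
    ``estimable=False`` on monotone likelihood / separation instead of
    raising.
    """
    ind = np.asarray(group_indicator, float)
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    if len(set(ind.tolist())) < 2:
        raise ValidationError("both indicator levels must be present")
    if events.sum() == 0:
        return {"hr": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                "p": np.nan, "estimable": False}
    df = pd.DataFrame({"t": times, "e": events.astype(int), "x": ind})
    cph = CoxPHFitter()
    try:
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="t", event_col="e")
    except (ConvergenceError, ValueError):
        return {"hr": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                "p": np.nan, "estimable": False}
    coef = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    if not np.isfinite(coef) or abs(coef) > 50 or se > 50:
        return {"hr": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                "p": np.nan, "estimable": False}
    z = 1.959963984540054
    return {
        "hr": float(np.exp(coef)),
        "ci_low": float(np.exp(coef - z * se)),
        "ci_high": float(np.exp(coef + z * se)),
        "p": float(cph.summary.loc["x", "p"]),
        "estimable": True,
    }


def survival_by_rank(clinical: pd.DataFrame, labels: pd.DataFrame, gene: str,
                     vaf_cut: float | None = None) -> dict:
    """Four-way rank comparison (both / dominant-only / secondary-only /
    neither) for one gene, with optional VAF strata.

    When ``vaf_cut`` is given, carriers are additionally split at the
    maximum observed VAF per patient: strictly above the cut vs at-or-below
    (the boundary belongs to the low stratum).
    """
    gene = gene.upper()
    glab = labels[labels["gene"] == gene]
    all_pats = set(clinical["patient_id"])
    if glab.empty:
        import warnings
        warnings.warn(f"gene {gene} absent from cohort; empty result")
        return {"groups": {}, "logrank": None, "pairwise_cox": {}, "vaf_strata": None}
    dom = set(glab.loc[glab["label"] == "dominant", "patient_id"])
    sec = set(glab.loc[glab["label"] == "secondary", "patient_id"])
    members = {
        "both": dom & sec,
        "dominant_only": dom - sec,
        "secondary_only": sec - dom,
        "neither": all_pats - dom - sec,
    }
    groups = {name: group_from_clinical(clinical, pats, name)
              for name, pats in members.items() if pats}
    lr = logrank(list(groups.values())) if len(groups) >= 2 else None

    pairwise = {}
    if "neither" in groups:
        ref = groups["neither"]
        for name, grp in groups.items():
            if name == "neither":
                continue
            ind = np.concatenate([np.ones(len(grp.times)), np.zeros(len(ref.times))])
            t = np.concatenate([grp.times, ref.times])
            e = np.concatenate([grp.events, ref.events])
            pairwise[f"{name}_vs_neither"] = cox_hr(ind, t, e)

    strata = None
    if vaf_cut is not None:
        vaf_col = "vaf_obs" if "vaf_obs" in glab.columns else None
        if vaf_col:
            per_pat = glab.groupby("patient_id")[vaf_col].max()
            high = set(per_pat[per_pat > vaf_cut].index)
            low = set(per_pat[per_pat <= vaf_cut].index)
            strata = {}
            if high:
                strata["vaf_high"] = group_from_clinical(clinical, high, f"VAF>{vaf_cut}")
            if low:
                strata["vaf_low"] = group_from_clinical(clinical, low, f"VAF<={vaf_cut}")
            if len(strata) == 2:
                g1, g0 = strata["vaf_high"], strata["vaf_low"]
                ind = np.concatenate([np.ones(len(g1.times)), np.zeros(len(g0.times))])
                strata["cox"] = cox_hr(ind,
                                       np.concatenate([g1.times, g0.times]),
                                       np.concatenate([g1.events, g0.events]))
    km = {name: km_estimate(grp) for name, grp in groups.items()}
    return {"groups": groups, "km": km, "logrank": lr,
            "pairwise_cox": pairwise, "vaf_strata": strata}
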