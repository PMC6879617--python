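"""Contingency-table analytics for lesion and mutation-rank associations.

All association questions reduce to 2×2 tables over patients: lesion
co-occurrence/mutual exclusivity, dominant→secondary mutation pairs,
phenotype odds ratios, and therapy-response associations.  Every table is
tested with a two-sided Fisher exact test (point-probability convention)
and corrected across the family of tests run together with the
Benjamini–Hochberg step-up rule.

The reported odds ratio is the cross-product (a·d)/(b·c), +inf when
b·c = 0 with a·d > 0 (the convention under which degenerate perfect
associations are printable).  A conditional-MLE estimator is available for
cross-checking via ``or_estimator="cmle"``.  Confidence intervals use the
Woolf log-OR ± 1.96·SE with a Haldane 0.5 continuity correction applied to
the CI only, never to the point estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from clonehier.cohort_model import ValidationError

RESPONDER_LEVELS = {"CR", "PR", "HI"}


@dataclass
class ContingencyResult:
    """One 2×2 association: counts, OR, Fisher p, BH q, direction."""

    label_a: str
    label_b: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p: float
    q: float = np.nan

    @property
    def direction(self) -> str:
        return "co_occurrence" if self.odds_ratio > 1 else "mutual_exclusivity"

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def cross_product_or(a: int, b: int, c: int, d: int) -> float:
    if b * c == 0:
        if a * d > 0:
            return float("inf")
        return float("nan")     # non-estimable (a zero row or column)
    return (a * d) / (b * c)


def fisher_2x2(a: int, b: int, c: int, d: int,
               or_estimator: str = "cross_product") -> tuple[float, float]:
    """Two-sided Fisher exact test on the table [[a, b], [c, d]].

    Returns ``(odds_ratio, p)``.  The p-value sums hypergeometric
    probabilities of all tables with the observed margins whose point
    probability does not exceed the observed one.
    """
    if min(a, b, c, d) < 0:
        raise ValidationError("negative cell count")
    if a + b + c + d == 0:
        raise ValidationError("all-zero contingency table")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if or_estimator == "cross_product":
        orr = cross_product_or(a, b, c, d)
    elif or_estimator == "cmle":
        orr = float(stats.contingency.odds_ratio([[a, b], [c, d]]).statistic)
    else:
        raise ValueError(f"unknown or_estimator {or_estimator!r}")
    return orr, float(p)


def woolf_ci(a: int, b: int, c: int, d: int, z: float = 1.959964) -> tuple[float, float]:
    """Woolf 95% CI for the OR, Haldane-corrected when any cell is zero."""
    cells = np.array([a, b, c, d], float)
    if (cells == 0).any():
        cells = cells + 0.5
    la, lb, lc, ld = np.log(cells)  # noqa: F841 - clarity
    log_or = np.log(cells[0] * cells[3] / (cells[1] * cells[2]))
    se = np.sqrt((1.0 / cells).sum())
    return float(np.exp(log_or - z * se)), float(np.exp(log_or + z * se))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-preserving."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _finish(results: list[ContingencyResult]) -> pd.DataFrame:
    if not results:
        return pd.DataFrame(columns=["label_a", "label_b", "a", "b", "c", "d",
                                     "odds_ratio", "p", "q", "direction"])
    q = bh_adjust([r.p for r in results])
    rows = []
    for r, qi in zip(results, q):
        r.q = float(qi)
        rows.append((r.label_a, r.label_b, r.a, r.b, r.c, r.d,
                     r.odds_ratio, r.p, r.q, r.direction))
    return pd.DataFrame(rows, columns=["label_a", "label_b", "a", "b", "c", "d",
                                       "odds_ratio", "p", "q", "direction"])


# ---------------------------------------------------------------------------
# dominant → secondary pairs
# ---------------------------------------------------------------------------

def pair_tables(labels: pd.DataFrame, min_freq: float = 0.01,
                q_co: float = 0.01, q_ex: float = 0.01,
                or_estimator: str = "cross_product") -> pd.DataFrame:
    """Exhaustive dominant→secondary gene-pair association tables.

    For each gene X dominant in strictly more than ``min_freq`` of
    patients, and each gene Y secondary in more than ``min_freq``:
    a = patients with X dominant and Y secondary; b = X dominant without Y
    secondary; c = Y secondary without X dominant; d = neither.  Fisher +
    BH over all tested pairs; ``significant`` flags q below the threshold
    for the observed direction.
    """
    if labels.empty:
        raise ValidationError("empty label table")
    patients = sorted(labels["patient_id"].unique())
    n = len(patients)
    dom_sets = {g: set(grp["patient_id"])
                for g, grp in labels[labels["label"] == "dominant"].groupby("gene")}
    sec_sets = {g: set(grp["patient_id"])
                for g, grp in labels[labels["label"] == "secondary"].groupby("gene")}
    dom_genes = sorted(g for g, s in dom_sets.items() if len(s) / n > min_freq)
    sec_genes = sorted(g for g, s in sec_sets.items() if len(s) / n > min_freq)
    results = []
    for gx in dom_genes:
        for gy in sec_genes:
            x, y = dom_sets[gx], sec_sets[gy]
            a = len(x & y)
            b = len(x - y)
            c = len(y - x)
            d = n - a - b - c
            orr, p = fisher_2x2(a, b, c, d, or_estimator)
            results.append(ContingencyResult(gx, gy, a, b, c, d, orr, p))
    out = _finish(results)
    out["significant"] = np.where(
        out["direction"] == "co_occurrence", out["q"] < q_co, out["q"] < q_ex
    )
    return out


# ---------------------------------------------------------------------------
# lesion-lesion correlation
# ---------------------------------------------------------------------------

def lesion_presence(cohort) -> pd.DataFrame:
    """Patient × lesion presence matrix (gene mutations + named CNAs)."""
    pats = cohort.patients
    cols = {}
    for g, grp in cohort.mutations.groupby("gene"):
        cols[g] = pd.Series(pats, index=pats).isin(set(grp["patient_id"]))
    if len(cohort.cn_segments):
        seg = cohort.cn_segments
        for (chrom, rc), grp in seg.groupby(["chrom", "region_class"]):
            if rc == "neutral":
                continue
            name = f"{rc}_chr{chrom}"
            cols[name] = pd.Series(pats, index=pats).isin(set(grp["sample"]))
    return pd.DataFrame(cols, index=pats).astype(bool)


def lesion_correlation(presence: pd.DataFrame, min_freq: float = 0.02,
                       q_co: float = 0.01, q_ex: float = 0.25) -> pd.DataFrame:
    """Pairwise lesion co-occurrence/exclusivity over a presence matrix.

    Lesions with frequency strictly above ``min_freq`` are tested pairwise
    (Fisher + BH); coexistence is flagged at q < ``q_co`` and exclusion at
    the laxer q < ``q_ex``.
    """
    n = len(presence)
    lesions = sorted(c for c in presence.columns if presence[c].mean() > min_freq)
    results = []
    for i, la in enumerate(lesions):
        for lb in lesions[i + 1:]:
            x, y = presence[la].to_numpy(), presence[lb].to_numpy()
            a = int((x & y).sum())
            b = int((x & ~y).sum())
            c = int((~x & y).sum())
            d = n - a - b - c
            orr, p = fisher_2x2(a, b, c, d)
            results.append(ContingencyResult(la, lb, a, b, c, d, orr, p))
    out = _finish(results)
    if len(out):
        out["significant"] = np.where(
            out["direction"] == "co_occurrence", out["q"] < q_co, out["q"] < q_ex
        )
    return out


# ---------------------------------------------------------------------------
# phenotype odds ratios
# ---------------------------------------------------------------------------

def _phenotype_flags(clinical: pd.DataFrame) -> pd.DataFrame:
    """MDS vs MDS/MPN flag (sAML mapped via antecedent class when known)."""
    clin = clinical.copy()
    if "antecedent" in clin.columns:
        saml = clin["diagnosis"] == "sAML"
        clin.loc[saml, "diagnosis"] = clin.loc[saml, "antecedent"]
    clin = clin[clin["diagnosis"].isin(["MDS", "MDS_MPN"])]
    clin["is_mdsmpn"] = clin["diagnosis"] == "MDS_MPN"
    clin["is_high_risk"] = clin["risk_group"] == "high"
    return clin


def phenotype_or(labels: pd.DataFrame, clinical: pd.DataFrame,
                 grouping: str = "pair_both_vs_neither",
                 min_freq: float = 0.01) -> pd.DataFrame:
    """Odds ratios of phenotype membership for lesion groups.

    ``grouping`` selects the carrier definition: ``single_lesion`` (any
    mutation in the gene), ``dominant_only`` / ``secondary_only`` (by rank)
    or ``pair_both_vs_neither`` (patients with both dominant X and
    secondary Y vs patients with neither; partial carriers are dropped).
    Returns one row per group × phenotype with OR, Woolf CI, Fisher p and
    BH q (family = all tests in the call).
    """
    if "risk_group" not in clinical.columns:
        raise ValidationError("clinical table lacks risk_group / phenotype columns")
    clin = _phenotype_flags(clinical)
    pats = set(clin["patient_id"])
    lab = labels[labels["patient_id"].isin(pats)]
    n = len(pats)

    groups: dict[str, tuple[set, set]] = {}   # name -> (carriers, comparators)
    if grouping == "single_lesion":
        for g, grp in lab.groupby("gene"):
            carriers = set(grp["patient_id"])
            if len(carriers) / n > min_freq:
                groups[g] = (carriers, pats - carriers)
    elif grouping in ("dominant_only", "secondary_only"):
        rank = grouping.split("_")[0]
        for g, grp in lab[lab["label"] == rank].groupby("gene"):
            carriers = set(grp["patient_id"])
            if len(carriers) / n > min_freq:
                groups[f"{rank}:{g}"] = (carriers, pats - carriers)
    elif grouping == "pair_both_vs_neither":
        dom = {g: set(grp["patient_id"])
               for g, grp in lab[lab["label"] == "dominant"].groupby("gene")}
        sec = {g: set(grp["patient_id"])
               for g, grp in lab[lab["label"] == "secondary"].groupby("gene")}
        for gx, x in sorted(dom.items()):
            if len(x) / n <= min_freq:
                continue
            for gy, y in sorted(sec.items()):
                if len(y) / n <= min_freq:
                    continue
                both = x & y
                neither = pats - x - y
                groups[f"{gx}>{gy}"] = (both, neither)
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    results, meta = [], []
    flags = clin.set_index("patient_id")
    for name, (carriers, comparators) in sorted(groups.items()):
        for pheno, col in (("MDS_vs_MDSMPN", "is_mdsmpn"), ("high_risk", "is_high_risk")):
            pos = set(flags.index[flags[col]])
            a = len(carriers & pos)
            b = len(carriers - pos)
            c = len(comparators & pos)
            d = len(comparators - pos)
            if a + b + c + d == 0:
                continue
            orr, p = fisher_2x2(a, b, c, d)
            results.append(ContingencyResult(name, pheno, a, b, c, d, orr, p))
            meta.append(woolf_ci(a, b, c, d))
    out = _finish(results)
    if len(out):
        out[["ci_low", "ci_high"]] = np.array(meta)
        out["estimable"] = np.isfinite(out["odds_ratio"]) & (out["odds_ratio"] > 0)
    return out


# ---------------------------------------------------------------------------
# HMA response
# ---------------------------------------------------------------------------

def hma_association(clinical: pd.DataFrame, labels: pd.DataFrame,
                    groupings: tuple[str, ...] = ("single_lesion", "dominant_only",
                                                  "secondary_only")) -> pd.DataFrame:
    """Response associations among HMA-treated patients.

    Responder = response in {CR, PR, HI}.  For each gene group, builds the
    responder-vs-nonresponder and CR-vs-non-CR 2×2 tables (carriers vs
    non-carriers among treated patients) with Fisher OR/p and BH q.
    """
    treated = clinical[clinical["hma_treated"]].copy()
    if treated.empty:
        raise ValidationError("no HMA-treated patients")
    treated["responder"] = treated["hma_response"].isin(RESPONDER_LEVELS)
    treated["cr"] = treated["hma_response"] == "CR"
    tpats = set(treated["patient_id"])
    lab = labels[labels["patient_id"].isin(tpats)]
    flags = treated.set_index("patient_id")

    groups: dict[str, set] = {}
    for grouping in groupings:
        if grouping == "single_lesion":
            for g, grp in lab.groupby("gene"):
                groups[g] = set(grp["patient_id"])
        else:
            rank = grouping.split("_")[0]
            for g, grp in lab[lab["label"] == rank].groupby("gene"):
                groups[f"{rank}:{g}"] = set(grp["patient_id"])

    results = []
    for name, carriers in sorted(groups.items()):
        rest = tpats - carriers
        for endpoint, col in (("responder", "responder"), ("CR", "cr")):
            pos = set(flags.index[flags[col]])
            a = len(carriers & pos)
            b = len(carriers - pos)
            c = len(rest & pos)
            d = len(rest - pos)
            if a + b == 0:
                continue
            orr, p = fisher_2x2(a, b, c, d)
            results.append(ContingencyResult(name, endpoint, a, b, c, d, orr, p))
    return _finish(results)


# ---------------------------------------------------------------------------
# packaged regression fixture
# ---------------------------------------------------------------------------

def load_table2_counts() -> pd.DataFrame:
    """Packaged 37-pair dominant→secondary count table for regression tests."""
    with resources.files("clonehier.data").joinpath("table2_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
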