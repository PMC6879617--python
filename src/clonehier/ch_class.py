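"""Clonal-hematopoiesis (CH) derivation classes from dominant mutations.

Genes frequently mutated in asymptomatic clonal hematopoiesis but enriched
there relative to MDS (DNMT3A, TET2, ASXL1, JAK2) mark an MDS case as
CH-related (CH_R) when they carry a dominant mutation.  Genes mutated at
similar rates in CH and MDS (TP53, SF3B1, SRSF2, GNB1, CBL) cannot
discriminate and mark a case as Overlapping; any other dominant gene marks
it CH-unrelated (CH_U).  Patients without mutations are Overlapping since
the criteria cannot separate them.

Precedence for mixed dominant gene sets (not fully pinned down by the
observable rules): any CH-related dominant gene ⇒ CH_R; otherwise any
dominant gene outside both sets ⇒ CH_U; otherwise Overlapping.  The
applied rule is recorded per patient for audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from clonehier.cohort_model import ValidationError

DEFAULT_CH_RELATED = frozenset({"DNMT3A", "TET2", "ASXL1", "JAK2"})
DEFAULT_OVERLAPPING = frozenset({"TP53", "SF3B1", "SRSF2", "GNB1", "CBL"})

CLASSES = ("CH_R", "CH_U", "Overlapping")


@dataclass(frozen=True)
class CHGeneSets:
    ch_related: frozenset = DEFAULT_CH_RELATED
    overlapping: frozenset = DEFAULT_OVERLAPPING

    def __post_init__(self) -> None:
        if self.ch_related & self.overlapping:
            raise ValidationError("CH-related and overlapping gene sets must be disjoint")


def classify_genes(dominant_genes: set[str], sets: CHGeneSets | None = None) -> str:
    """Classify one patient from the genes carrying a dominant mutation."""
    sets = sets or CHGeneSets()
    g = {str(x).upper() for x in dominant_genes}
    if not g:
        return "Overlapping"
    if g & sets.ch_related:
        return "CH_R"
    if g <= sets.overlapping:
        return "Overlapping"
    return "CH_U"


def classify_patient(architecture, sets: CHGeneSets | None = None) -> str:
    """Classify from a fitted :class:`~clonehier.clonal_dp.ClonalArchitecture`."""
    dominant = {m.gene for m, lab in architecture.iter_labeled() if lab == "dominant"}
    return classify_genes(dominant, sets)


def classify_cohort(labels: pd.DataFrame, sets: CHGeneSets | None = None) -> pd.DataFrame:
    """Classify every patient from a label table.

    ``labels`` needs columns ``patient_id``, ``gene``, ``label``; patients
    present in the table are classified from their dominant genes.
    Returns ``patient_id``, ``ch_class``.
    """
    rows = []
    for pid, grp in labels.groupby("patient_id"):
        dom = set(grp.loc[grp["label"] == "dominant", "gene"])
        rows.append((pid, classify_genes(dom, sets)))
    return pd.DataFrame(rows, columns=["patient_id", "ch_class"])


def ch_profile(classes: pd.DataFrame, labels: pd.DataFrame,
               clinical: pd.DataFrame) -> dict:
    """Compare CH classes: sizes, gene composition, secondary-gene Fisher/BH.

    Returns a dict of DataFrames: ``sizes``, ``dominant_composition``,
    ``secondary_freq`` (CH_R vs CH_U with Fisher p and BH q), ``clinical``
    summaries, and ``survival_groups`` (patient lists per class for the
    outcomes module).
    """
    from clonehier.cooccur import bh_adjust, fisher_2x2

    merged = labels.merge(classes, on="patient_id")
    n_total = classes["patient_id"].nunique()
    sizes = (
        classes.groupby("ch_class")["patient_id"].nunique()
        .reindex(CLASSES, fill_value=0).rename("n").reset_index()
    )
    sizes["fraction"] = sizes["n"] / max(n_total, 1)

    dom = merged[merged["label"] == "dominant"]
    comp = (
        dom.groupby(["ch_class", "gene"])["patient_id"].nunique()
        .rename("n_patients").reset_index()
    )

    # secondary-gene frequencies, CH_R vs CH_U
    pat_r = set(classes.loc[classes["ch_class"] == "CH_R", "patient_id"])
    pat_u = set(classes.loc[classes["ch_class"] == "CH_U", "patient_id"])
    sec = merged[merged["label"] == "secondary"]
    rows = []
    for gene, grp in sec.groupby("gene"):
        carriers = set(grp["patient_id"])
        a = len(carriers & pat_r)
        b = len(pat_r - carriers)
        c = len(carriers & pat_u)
        d = len(pat_u - carriers)
        if a + c == 0 or not pat_r or not pat_u:
            continue
        orr, p = fisher_2x2(a, b, c, d)
        rows.append((gene, a, len(pat_r), c, len(pat_u), orr, p))
    sec_freq = pd.DataFrame(
        rows, columns=["gene", "n_CH_R", "total_CH_R", "n_CH_U", "total_CH_U",
                       "odds_ratio", "p"]
    )
    if len(sec_freq):
        sec_freq["q"] = bh_adjust(sec_freq["p"].to_numpy())
        sec_freq["significant"] = sec_freq["q"] < 0.01

    clin = clinical.merge(classes, on="patient_id")
    clin_summary = clin.groupby("ch_class").agg(
        n=("patient_id", "nunique"),
        median_os=("os_months", "median"),
        events=("os_event", "sum"),
        low_risk_frac=("risk_group", lambda s: float(np.mean(s == "low"))),
        mdsmpn_frac=("diagnosis", lambda s: float(np.mean(s == "MDS_MPN"))),
    ).reset_index()

    survival_groups = {
        cls: sorted(classes.loc[classes["ch_class"] == cls, "patient_id"])
        for cls in CLASSES
    }
    return {
        "sizes": sizes,
        "dominant_composition": comp,
        "secondary_freq": sec_freq,
        "clinical": clin_summary,
        "survival_groups": survival_groups,
    }
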