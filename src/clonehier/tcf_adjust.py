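"""Observed VAF ↔ tumor-cell fraction (TCF) mapping under copy number.

For a heterozygous somatic mutation, the fraction of cells carrying the
mutation (TCF, also written aVAF) follows from the observed variant allele
frequency and the copy-number context of the locus:

==========  ======================================  =========================
region      TCF from VAF                            condition
==========  ======================================  =========================
neutral     2·VAF
deletion    TCN·VAF
UPD late    2·VAF − 1 + AsCN                        VAF > (1 − AsCN)/2
UPD early   2·VAF                                   VAF ≤ (1 − AsCN)/2
gain        3·VAF                                   TCN fixed at 3
==========  ======================================  =========================

"UPD late" means the uniparental disomy arose after the mutation (the
mutant allele was duplicated); "UPD early" means the mutation landed on one
copy after the UPD.  The gain branch uses a conventional TCN of 3 because
the true total copy number of a gained region cannot be estimated from
depth alone; its raw value exceeds 1 for VAF > 1/3 and is clamped (flagged).

The two UPD branches are discontinuous at the threshold VAF = (1 − AsCN)/2
(left limit 1 − AsCN, right limit 0 as TCF contributions).  The mapping is
implemented exactly as stated, with the boundary itself assigned to the
early branch (continuous with the neutral case); the ``clamped`` flag and
``branch_used`` field give a per-call audit trail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from clonehier.cohort_model import CopyNumberState, MutationCall, ValidationError

BRANCHES = ("neutral", "deletion", "upd_early", "upd_late", "gain")

#: conventional total copy number assumed for gained regions
GAIN_TCN = 3.0


@dataclass
class AdjustedMutation:
    """A mutation call annotated with its estimated tumor-cell fraction."""

    call: MutationCall
    tcf: float
    branch_used: str
    clamped: bool


def _select_branch(vaf: float, cn: CopyNumberState) -> str:
    if cn.region_class == "neutral":
        return "neutral"
    if cn.region_class == "deletion":
        return "deletion"
    if cn.region_class == "gain":
        return "gain"
    # UPD: boundary goes to the early branch (continuous with neutral)
    return "upd_late" if vaf > 0.5 * (1.0 - cn.ascn) else "upd_early"


def _raw_tcf(vaf: float, cn: CopyNumberState, branch: str) -> float:
    if branch in ("neutral", "upd_early"):
        return 2.0 * vaf
    if branch == "deletion":
        return cn.tcn * vaf
    if branch == "upd_late":
        return 2.0 * vaf - 1.0 + cn.ascn
    if branch == "gain":
        return GAIN_TCN * vaf
    raise ValueError(f"unknown branch {branch!r}")


def tcf_from_vaf(vaf: float, cn: CopyNumberState | None = None) -> tuple[float, str, bool]:
    """Branch-resolved TCF for a bare VAF; returns (tcf, branch, clamped)."""
    cn = cn if cn is not None else CopyNumberState()
    if not 0.0 <= vaf <= 1.0:
        raise ValidationError("vaf outside [0, 1]")
    branch = _select_branch(vaf, cn)
    raw = _raw_tcf(vaf, cn, branch)
    tcf = min(1.0, max(0.0, raw))
    return tcf, branch, tcf != raw


def estimate_tcf(call: MutationCall, cn: CopyNumberState | None = None) -> AdjustedMutation:
    """Estimate the tumor-cell fraction carrying ``call``.

    When no copy-number state is given the locus is treated as neutral.
    The result is clamped to [0, 1]; ``clamped`` records whether the raw
    branch value fell outside.
    """
    cn = cn if cn is not None else call.cn_state
    vaf = call.vaf_obs
    if not 0.0 <= vaf <= 1.0:
        raise ValidationError("vaf_obs outside [0, 1]")
    branch = _select_branch(vaf, cn)
    raw = _raw_tcf(vaf, cn, branch)
    tcf = min(1.0, max(0.0, raw))
    return AdjustedMutation(call=call, tcf=tcf, branch_used=branch, clamped=tcf != raw)


def vaf_expected(phi: float, cn: CopyNumberState | None = None, branch: str = "neutral") -> float:
    """Expected VAF of a mutation present in a fraction ``phi`` of cells.

    Exact algebraic inverse of the branch formulas in :func:`estimate_tcf`,
    used as the mean of the Beta-Binomial emission in the clonal
    clustering.  Result is clipped to [0, 1].
    """
    if not 0.0 <= phi <= 1.0:
        raise ValidationError("phi outside [0, 1]")
    if branch not in BRANCHES:
        raise ValueError(f"unknown branch {branch!r}")
    cn = cn if cn is not None else CopyNumberState()
    if branch in ("neutral", "upd_early"):
        v = phi / 2.0
    elif branch == "deletion":
        if cn.tcn == 0:
            raise ValidationError("deletion branch with tcn = 0")
        v = phi / cn.tcn
    elif branch == "upd_late":
        v = (phi + 1.0 - cn.ascn) / 2.0
    else:  # gain
        v = phi / GAIN_TCN
    return float(np.clip(v, 0.0, 1.0))


def adjust_table(mutations: pd.DataFrame) -> pd.DataFrame:
    """Vectorised :func:`estimate_tcf` over a mutation table.

    Expects columns ``vaf_obs``/(``alt_reads``, ``depth``) plus
    ``region_class``, ``tcn``, ``ascn`` (see
    :func:`clonehier.cohort_model.attach_cn_states`); adds ``tcf``,
    ``branch_used``, ``clamped``.
    """
    out = mutations.copy()
    if "vaf_obs" not in out.columns:
        out["vaf_obs"] = out["alt_reads"] / out["depth"]
    for col, default in (("region_class", "neutral"), ("tcn", 2.0), ("ascn", 1.0)):
        if col not in out.columns:
            out[col] = default
    vaf = out["vaf_obs"].to_numpy(float)
    tcn = out["tcn"].to_numpy(float)
    ascn = out["ascn"].to_numpy(float)
    rc = out["region_class"].to_numpy(object)

    branch = np.where(rc == "deletion", "deletion",
             np.where(rc == "gain", "gain",
             np.where(rc == "UPD",
                      np.where(vaf > 0.5 * (1.0 - ascn), "upd_late", "upd_early"),
                      "neutral")))
    raw = np.where(branch == "deletion", tcn * vaf,
          np.where(branch == "gain", GAIN_TCN * vaf,
          np.where(branch == "upd_late", 2.0 * vaf - 1.0 + ascn, 2.0 * vaf)))
    tcf = np.clip(raw, 0.0, 1.0)
    out["tcf"] = tcf
    out["branch_used"] = branch
    out["clamped"] = tcf != raw
    return out
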