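"""Shared domain types, standard-format IO, and variant-level filters.

The working containers are pandas DataFrames with fixed schemas; the
dataclasses below are the typed record views used by the arithmetic layers
(:mod:`clonehier.tcf_adjust`, :mod:`clonehier.clonal_dp`).

Schemas
-------
mutation table (TSV header)::

    patient_id  gene  variant_class  chrom  pos  ref  alt  alt_reads  depth  bidirectional

SEG table::

    sample  chrom  start  end  region_class  tcn  ascn

clinical table::

    patient_id  diagnosis  ipssr_score  os_months  os_event  hma_treated  hma_response

Coordinates are 1-based inclusive (SEG convention); a mutation overlaps a
segment when ``start <= pos <= end`` on the same chromosome and patient.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MUTATION_COLUMNS = [
    "patient_id", "gene", "variant_class", "chrom", "pos", "ref", "alt",
    "alt_reads", "depth", "bidirectional",
]
SEG_COLUMNS = ["sample", "chrom", "start", "end", "region_class", "tcn", "ascn"]
CLINICAL_COLUMNS = [
    "patient_id", "diagnosis", "ipssr_score", "os_months", "os_event",
    "hma_treated", "hma_response",
]

VARIANT_CLASSES = {"missense", "truncating", "splice", "canonical_hotspot", "other"}
REGION_CLASSES = {"neutral", "deletion", "gain", "UPD"}
RESPONSE_LEVELS = {"CR", "PR", "HI", "none", "NA"}

#: IPSS-R threshold separating lower- from higher-risk disease.
IPSSR_LOW_RISK_MAX = 3.5


class SchemaError(ValueError):
    """A required column or field is missing from an input table."""


class ValidationError(ValueError):
    """An input value violates a domain invariant."""


@dataclass(frozen=True)
class CopyNumberState:
    """Copy-number context of a locus.

    ``tcn`` is the total copy number and ``ascn`` the minor allele-specific
    copy number in [0, 1].  Gains carry ``tcn = 3`` by convention since the
    true total copy number of a gained region cannot be estimated from
    depth alone.
    """

    region_class: str = "neutral"
    tcn: float = 2.0
    ascn: float = 1.0

    def __post_init__(self) -> None:
        if self.region_class not in REGION_CLASSES:
            raise ValidationError(f"unknown region_class {self.region_class!r}")
        if self.tcn < 0:
            raise ValidationError("tcn must be non-negative")
        if not 0.0 <= self.ascn <= 1.0:
            raise ValidationError("ascn must lie in [0, 1]")
        checks = {
            "neutral": self.tcn == 2,
            "UPD": self.tcn == 2,
            "deletion": self.tcn < 2,
            "gain": self.tcn == 3,
        }
        if not checks[self.region_class]:
            raise ValidationError(
                f"tcn={self.tcn} inconsistent with region_class={self.region_class}"
            )


NEUTRAL = CopyNumberState()


@dataclass
class MutationCall:
    """One somatic variant call in one patient."""

    patient_id: str
    gene: str
    variant_class: str = "missense"
    chrom: str = "."
    pos: int = 0
    ref: str = "N"
    alt: str = "N"
    alt_reads: int = 0
    depth: int = 1
    bidirectional: bool = True
    cn_state: CopyNumberState = field(default_factory=lambda: NEUTRAL)

    def __post_init__(self) -> None:
        self.gene = str(self.gene).upper()
        if self.depth <= 0:
            raise ValidationError(f"{self.patient_id}/{self.gene}: depth must be positive")
        if self.alt_reads < 0:
            raise ValidationError(f"{self.patient_id}/{self.gene}: negative alt_reads")
        if self.alt_reads > self.depth:
            raise ValidationError(
                f"{self.patient_id}/{self.gene}: alt_reads {self.alt_reads} exceeds depth {self.depth}"
            )

    @property
    def vaf_obs(self) -> float:
        return self.alt_reads / self.depth


@dataclass
class ClinicalAnnotation:
    """Per-patient clinical annotation row."""

    patient_id: str
    diagnosis: str
    ipssr_score: float
    os_months: float
    os_event: bool
    hma_treated: bool = False
    hma_response: str = "NA"

    def __post_init__(self) -> None:
        if self.diagnosis not in {"MDS", "MDS_MPN", "sAML"}:
            raise ValidationError(f"unknown diagnosis {self.diagnosis!r}")
        if self.ipssr_score < 0 or self.os_months < 0:
            raise ValidationError("ipssr_score and os_months must be non-negative")
        if self.hma_response not in RESPONSE_LEVELS:
            raise ValidationError(f"unknown hma_response {self.hma_response!r}")
        if self.hma_response != "NA" and not self.hma_treated:
            raise ValidationError("hma_response set for an untreated patient")

    @property
    def risk_group(self) -> str:
        return "low" if self.ipssr_score <= IPSSR_LOW_RISK_MAX else "high"


@dataclass
class CohortTable:
    """A cohort: mutation calls, clinical rows, copy-number segments."""

    mutations: pd.DataFrame
    clinical: pd.DataFrame
    cn_segments: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.mutations["patient_id"]) - set(self.clinical["patient_id"])
        if missing:
            raise ValidationError(
                f"mutations reference patients without clinical rows: {sorted(missing)[:5]}"
            )

    @property
    def patients(self) -> list[str]:
        return list(self.clinical["patient_id"])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {', '.join(missing)}")


def read_mutation_table(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    """Read a mutation call table (TSV, or single-sample VCF with AD/DP).

    Gene symbols are upper-cased; VAF is always recomputed from the read
    counts (counts are the primitive the clustering consumes, so they win
    over any stated VAF column).
    """
    if format == "vcf":
        return _read_mutation_vcf(path)
    if format != "tsv":
        raise ValueError(f"unknown format {format!r}")
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "chrom": str})
    if df.empty and not df.columns.size:
        raise SchemaError(f"{path}: empty file without header")
    _require_columns(df, [c for c in MUTATION_COLUMNS if c != "bidirectional"], "mutation table")
    if "bidirectional" not in df.columns:
        df["bidirectional"] = True
    df = df[MUTATION_COLUMNS].copy()
    df["gene"] = df["gene"].astype(str).str.upper()
    df["alt_reads"] = df["alt_reads"].astype(int)
    df["depth"] = df["depth"].astype(int)
    df["bidirectional"] = df["bidirectional"].astype(bool)
    if (df["alt_reads"] < 0).any() or (df["depth"] <= 0).any():
        raise ValidationError("negative alt_reads or non-positive depth in mutation table")
    if (df["alt_reads"] > df["depth"]).any():
        bad = df.loc[df["alt_reads"] > df["depth"]].iloc[0]
        raise ValidationError(
            f"alt_reads exceeds depth for {bad['patient_id']}/{bad['gene']}"
        )
    df["vaf_obs"] = df["alt_reads"] / df["depth"]
    return df


def _read_mutation_vcf(path: str | Path) -> pd.DataFrame:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("VCF ingestion requires cyvcf2") from exc
    rows = []
    vcf = VCF(str(path))
    if len(vcf.samples) != 1:
        raise ValidationError("VCF ingestion is restricted to single-sample files")
    sample = vcf.samples[0]
    for rec in vcf:
        ad = rec.format("AD")
        dp = rec.format("DP")
        if ad is None or dp is None:
            raise SchemaError("VCF record lacks AD/DP format fields")
        alt_reads = int(ad[0][1])
        depth = int(dp[0][0])
        gene = dict(rec.INFO).get("GENE", ".")
        rows.append(
            dict(
                patient_id=sample, gene=str(gene).upper(), variant_class="other",
                chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=rec.ALT[0],
                alt_reads=alt_reads, depth=depth, bidirectional=True,
            )
        )
    df = pd.DataFrame(rows, columns=MUTATION_COLUMNS)
    df["vaf_obs"] = df["alt_reads"] / df["depth"] if len(df) else pd.Series(dtype=float)
    return df


def read_seg(path: str | Path) -> pd.DataFrame:
    """Read a SEG file (1-based inclusive coordinates)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    _require_columns(df, SEG_COLUMNS, "SEG file")
    bad = set(df["region_class"]) - REGION_CLASSES
    if bad:
        raise ValidationError(f"unknown region_class values: {sorted(bad)}")
    return df[SEG_COLUMNS].copy()


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    _require_columns(df, CLINICAL_COLUMNS, "clinical table")
    df = df[CLINICAL_COLUMNS].copy()
    df["os_event"] = df["os_event"].astype(bool)
    df["hma_treated"] = df["hma_treated"].astype(bool)
    df["risk_group"] = np.where(df["ipssr_score"] <= IPSSR_LOW_RISK_MAX, "low", "high")
    return df


def attach_cn_states(mutations: pd.DataFrame, segments: pd.DataFrame) -> pd.DataFrame:
    """Annotate each mutation with its overlapping copy-number state.

    Point-in-interval match (1-based inclusive) on the same patient; calls
    without an overlapping segment default to copy-neutral.  Adds columns
    ``region_class``, ``tcn``, ``ascn``.
    """
    out = mutations.copy()
    out["region_class"] = "neutral"
    out["tcn"] = 2.0
    out["ascn"] = 1.0
    if segments is None or segments.empty:
        return out
    seg_by_patient = dict(tuple(segments.groupby("sample")))
    for idx, row in out.iterrows():
        segs = seg_by_patient.get(row["patient_id"])
        if segs is None:
            continue
        hit = segs[
            (segs["chrom"].astype(str) == str(row["chrom"]))
            & (segs["start"] <= row["pos"])
            & (segs["end"] >= row["pos"])
        ]
        if len(hit):
            h = hit.iloc[0]
            out.loc[idx, ["region_class", "tcn", "ascn"]] = (
                h["region_class"], float(h["tcn"]), float(h["ascn"]),
            )
    return out


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_variants(
    calls: pd.DataFrame, min_depth: int = 20, min_alt: int = 5
) -> pd.DataFrame:
    """Apply the variant-level read-support filters.

    Retains calls with ``depth >= min_depth`` (default 20), ``alt_reads >=
    min_alt`` (default 5) and bidirectional read support.  Synonymous
    variants never enter a mutation table (enforced at read time through
    the ``variant_class`` vocabulary), so no class filter is applied here.
    Idempotent by construction.
    """
    keep = (
        (calls["depth"] >= min_depth)
        & (calls["alt_reads"] >= min_alt)
        & calls["bidirectional"]
    )
    return calls.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# result export
# ---------------------------------------------------------------------------

def write_results(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    config: dict | None = None,
) -> dict:
    """Write named result tables as TSV plus a JSON manifest.

    The manifest records each file name, its row count, a sha256 of its
    bytes, and a hash of the (JSON-serialised) config so that re-runs with
    identical inputs are verifiable as byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config_blob = json.dumps(config or {}, sort_keys=True, default=str)
    manifest: dict = {
        "config_hash": hashlib.sha256(config_blob.encode()).hexdigest()[:16],
        "files": [],
    }
    for name, df in sorted(tables.items()):
        fname = f"{name}.tsv"
        path = out_dir / fname
        df.to_csv(path, sep="\t", index=False)
        manifest["files"].append(
            {
                "name": fname,
                "rows": int(len(df)),
                "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
            }
        )
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
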