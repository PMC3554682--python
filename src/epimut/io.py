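"""File formats: design/comparison TSVs, cohort CSV, BED and summary tables.

All genomic coordinates are 0-based half-open, in files as in memory. The
cohort CSV uses the sentinel ``ND`` for not-determined cells; the disease
matrix CSV mirrors the field convention of '+' (present), '-' (absent) and
blank (not determined).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .medip import DMR_COLUMNS
from .phenotype import ABSENT, DiseaseMatrix, ND, PRESENT
from .simulate import ArrayDesign, CohortTable, HybridizationSet, SpikePlan

__all__ = [
    "RunConfig",
    "write_design",
    "read_design",
    "write_comparisons",
    "read_comparisons",
    "write_cohort",
    "read_cohort",
    "write_bed",
    "read_bed",
    "write_dmr_table",
    "write_disease_matrix",
    "read_disease_matrix",
    "bed_score",
]

ND_SENTINEL = "ND"
DESIGN_COLUMNS = ["probe_id", "chrom", "start", "end", "promoter_id", "gene_id"]
PROMOTER_COLUMNS = ["promoter_id", "chrom", "tss", "strand", "region_start", "region_end", "gene_id"]
COMPARISON_COLUMNS = ["probe_id", "cy5", "cy3"]
_META_COLS = ("animal_id", "lineage", "generation", "sex", "litter_id")


def write_design(design: ArrayDesign, path, promoters_path=None) -> None:
    """Write probes (and optionally promoters) as tab-separated tables."""
    design.probes[DESIGN_COLUMNS].to_csv(path, sep="\t", index=False)
    if promoters_path is not None:
        design.promoters[PROMOTER_COLUMNS].to_csv(promoters_path, sep="\t", index=False)


def read_design(path, promoters_path=None) -> ArrayDesign:
    """Read a probe TSV (0-based half-open coordinates) back into a design.

    Without a promoter table, promoter regions are reconstructed as the
    span of their probes (TSS/strand unknown -> TSS at region start, '+').
    """
    probes = pd.read_csv(path, sep="\t")
    missing = [c for c in DESIGN_COLUMNS if c not in probes.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    for col in ("start", "end"):
        if not pd.api.types.is_integer_dtype(probes[col]):
            coerced = pd.to_numeric(probes[col], errors="coerce")
            bad = coerced.isna() | (coerced != coerced.round())
            line = (int(np.flatnonzero(bad)[0]) + 2) if bad.any() else 2
            raise ValueError(f"{path}: line {line}: non-integer coordinate in {col!r}")
    neg = probes["start"] < 0
    if neg.any():
        raise ValueError(f"{path}: line {int(np.flatnonzero(neg)[0]) + 2}: negative coordinate")
    inv = probes["end"] <= probes["start"]
    if inv.any():
        raise ValueError(
            f"{path}: line {int(np.flatnonzero(inv)[0]) + 2}: empty or inverted interval"
        )
    if promoters_path is not None:
        promoters = pd.read_csv(promoters_path, sep="\t")
    else:
        agg = probes.groupby("promoter_id", sort=False).agg(
            chrom=("chrom", "first"),
            region_start=("start", "min"),
            region_end=("end", "max"),
            gene_id=("gene_id", "first"),
        )
        promoters = agg.reset_index()
        promoters["tss"] = promoters["region_start"]
        promoters["strand"] = "+"
        promoters = promoters[PROMOTER_COLUMNS]
    design = ArrayDesign(probes=probes, promoters=promoters)
    design.validate()
    return design


def write_comparisons(hybs: HybridizationSet, out_dir) -> list[Path]:
    """Write one TSV per comparison (probe_id, cy5, cy3); returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for cid, frame in hybs.comparisons.items():
        p = out_dir / f"comparison_{cid}.tsv"
        frame[COMPARISON_COLUMNS].to_csv(p, sep="\t", index=False)
        paths.append(p)
    return paths


def read_comparisons(paths) -> dict[str, pd.DataFrame]:
    """Read comparison TSVs into {comparison_id: channel table}."""
    out = {}
    universe = None
    for i, path in enumerate(paths):
        frame = pd.read_csv(path, sep="\t")
        missing = [c for c in COMPARISON_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"{path}: missing column(s) {missing}")
        bad = (frame["cy5"] <= 0) | (frame["cy3"] <= 0)
        if bad.any():
            line = int(np.flatnonzero(bad)[0]) + 2
            raise ValueError(f"{path}: line {line}: non-positive intensity")
        cid = Path(path).stem.replace("comparison_", "") or f"c{i + 1}"
        probes = frozenset(frame["probe_id"])
        if universe is None:
            universe = probes
        elif probes != universe:
            raise ValueError(f"{path}: probe universe differs from first comparison")
        out[cid] = frame
    if not out:
        raise ValueError("no comparison files given")
    return out


def write_cohort(cohort: CohortTable, path) -> None:
    """Write the cohort CSV with the ``ND`` sentinel for missing cells."""
    df = cohort.animals.copy()
    df["adiposity_flag"] = df["adiposity_flag"].map(
        lambda v: ND_SENTINEL if v is None or (isinstance(v, float) and math.isnan(v)) else str(bool(v))
    )
    df["tumor_status"] = df["tumor_status"].map(
        {PRESENT: "+", ABSENT: "-"}
    ).fillna(ND_SENTINEL)
    df.to_csv(path, index=False, na_rep=ND_SENTINEL)


def read_cohort(path) -> CohortTable:
    """Read a cohort CSV (``ND`` = not determined) into a CohortTable."""
    df = pd.read_csv(path, na_values=[ND_SENTINEL], keep_default_na=False)
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if "adiposity_flag" in df.columns:
        df["adiposity_flag"] = df["adiposity_flag"].map(
            lambda v: np.nan if (isinstance(v, float) and math.isnan(v)) else str(v) == "True"
        )
    if "tumor_status" in df.columns:
        df["tumor_status"] = df["tumor_status"].map({"+": PRESENT, "-": ABSENT}).fillna(ND)
    for col in df.columns:
        if col in _META_COLS or col in ("adiposity_flag", "tumor_status"):
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(np.flatnonzero(bad)[0]) + 2
            raise ValueError(f"{path}: line {line}: malformed value in {col!r}")
        df[col] = coerced
        if col.endswith(("_count", "_lesions")) or "_lesions_obs" in col:
            if (coerced.dropna() < 0).any():
                line = int(np.flatnonzero(coerced < 0)[0]) + 2
                raise ValueError(f"{path}: line {line}: negative count in {col!r}")
    return CohortTable(animals=df, truth=pd.DataFrame(), metadata={"source": str(path)})


def bed_score(min_p: float) -> int:
    """BED score column: -10*log10(min_p), capped at 1000."""
    if min_p <= 0:
        return 1000
    return int(min(round(-10.0 * math.log10(min_p)), 1000))


def _chrom_key(chrom: str):
    tail = chrom[3:] if chrom.startswith("chr") else chrom
    return (0, int(tail)) if tail.isdigit() else (1, tail)


def write_bed(dmrs: pd.DataFrame, path) -> None:
    """Write DMRs as 6-column BED, sorted by chromosome then start.

    name = promoter|gene, score = -10*log10(min_p) capped at 1000, strand =
    direction of the methylation change.
    """
    rows = []
    for _, d in dmrs.iterrows():
        rows.append(
            (
                d["chrom"],
                int(d["start"]),
                int(d["end"]),
                f"{d['promoter_id']}|{d['gene_id']}",
                bed_score(float(d["min_p"])),
                d["sign"],
            )
        )
    rows.sort(key=lambda r: (_chrom_key(r[0]), r[1]))
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


def read_bed(path) -> pd.DataFrame:
    """Read a 6-column BED written by :func:`write_bed`."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path}: line {ln}: expected 6 columns")
            chrom, start, end, name, score, strand = parts
            prom, _, gene = name.partition("|")
            rows.append((chrom, int(start), int(end), prom, gene, int(score), strand))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "promoter_id", "gene_id", "score", "strand"]
    )


def write_dmr_table(dmrs: pd.DataFrame, path, gene_categories: dict | None = None) -> None:
    """Full DMR table: category, chrom, start, stop, gene id, p-value, gene name."""
    gene_categories = gene_categories or {}
    out = pd.DataFrame(
        {
            "category": dmrs["gene_id"].map(lambda g: gene_categories.get(g, "unknown")),
            "chrom": dmrs["chrom"],
            "start": dmrs["start"].astype(int),
            "stop": dmrs["end"].astype(int),
            "gene_id": dmrs["gene_id"],
            "p_value": dmrs["min_p"],
            "gene_name": dmrs["gene_id"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


_STATUS_TO_MARK = {PRESENT: "+", ABSENT: "-", ND: ""}
_MARK_TO_STATUS = {"+": PRESENT, "-": ABSENT, "": ND}


def write_disease_matrix(matrix: DiseaseMatrix, path) -> None:
    """Disease matrix CSV with '+'/'-'/blank cells and an n_diseases column."""
    marks = matrix.statuses.replace(_STATUS_TO_MARK)
    out = matrix.meta.join(marks)
    out["n_diseases"] = matrix.n_diseases
    out.to_csv(path, na_rep="")


def read_disease_matrix(path) -> DiseaseMatrix:
    df = pd.read_csv(path, index_col=0, keep_default_na=False)
    meta_cols = [c for c in ("lineage", "generation", "sex", "litter_id") if c in df.columns]
    disease_cols = [c for c in df.columns if c not in meta_cols + ["n_diseases"]]
    statuses = df[disease_cols].apply(lambda col: col.map(lambda v: _MARK_TO_STATUS.get(str(v), ND)))
    return DiseaseMatrix(statuses=statuses, meta=df[meta_cols])


@dataclass
class RunConfig:
    """Resolved parameters of a pipeline run; unknown keys are rejected."""

    seed: int = 0
    out_dir: str = "epimut_out"
    n_promoters: int = 300
    n_comparisons: int = 3
    noise_sd: float = 0.2
    dye_bias: float = 0.0
    window_bp: int = 600
    min_probes: int = 3
    alpha: float = 0.05
    normalization: str = "median_center"
    n_per_cell: int = 15
    litters_per_cell: int = 4
    k_sd_obesity: float = 1.0
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k) for k in self.__dataclass_fields__ if k != "extra"
        }
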