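"""Disease/abnormality classification from cohort endpoints.

Every rule keys off a control-lineage reference: the sample mean and SD of
an endpoint in control animals of the same generation and sex define a
normal range of mean ± 2 SD. Values strictly below the range are abnormal
for "loss"-type endpoints (early puberty, primordial follicle loss), values
strictly above for "excess"-type endpoints (delayed puberty, polycystic
ovary); the boundary itself is always normal. Histopathology uses each
observer's own control cutoff (mean + 2 SD of lesion counts) and declares a
tissue diseased only when at least two of three observers agree. Obesity
requires both the gross adiposity observation and a body-weight increase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import CohortTable, LESION_ORGANS, N_OBSERVERS

__all__ = [
    "ControlReference",
    "DiseaseMatrix",
    "control_reference",
    "control_references",
    "classify_puberty",
    "classify_follicle_loss",
    "classify_polycystic",
    "consensus_histopathology",
    "classify_obesity",
    "build_disease_matrix",
    "DISEASES",
]

PRESENT, ABSENT, ND = "present", "absent", "not_determined"

DISEASES = (
    "pubertal_abnormality",
    "follicle_loss",
    "polycystic_ovary",
    "testis_disease",
    "prostate_disease",
    "kidney_disease",
    "obesity",
    "tumor",
)


@dataclass(frozen=True)
class ControlReference:
    """Control mean/SD for one endpoint and the ±2 SD normal range."""

    endpoint: str
    mean: float
    sd: float
    low: float
    high: float
    n: int


def control_reference(values, endpoint: str = "") -> ControlReference:
    """Sample mean and SD (n-1 denominator) of control values; range = mean ± 2 SD."""
    arr = np.asarray([v for v in np.asarray(values, dtype=float) if math.isfinite(v)])
    if len(arr) < 2:
        raise ValueError(f"reference undefined for {endpoint!r}: need >=2 control values")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    return ControlReference(
        endpoint=endpoint, mean=mean, sd=sd, low=mean - 2 * sd, high=mean + 2 * sd, n=len(arr)
    )


def classify_puberty(day: float, ref: ControlReference) -> str:
    """Pubertal onset below the normal range is early, above it delayed."""
    if not math.isfinite(day):
        return ND
    if day < ref.low:
        return "early"
    if day > ref.high:
        return "delayed"
    return "normal"


def classify_follicle_loss(count: float, ref: ControlReference) -> bool:
    """Primordial follicle loss: count strictly less than control mean - 2 SD."""
    return math.isfinite(count) and count < ref.low


def classify_polycystic(cysts: float, ref: ControlReference) -> bool:
    """Polycystic ovary: cysts per section strictly more than control mean + 2 SD."""
    return math.isfinite(cysts) and cysts > ref.high


def consensus_histopathology(lesion_counts, observer_refs, min_agree: int = 2) -> bool:
    """Two-of-three observer consensus on lesion counts.

    Each observer's call is count > that observer's own control cutoff
    (mean + 2 SD); the tissue is diseased when at least ``min_agree``
    observers call it.
    """
    counts = list(lesion_counts)
    refs = list(observer_refs)
    if len(counts) != len(refs):
        raise ValueError(
            f"observer mismatch: {len(counts)} counts vs {len(refs)} references"
        )
    calls = sum(
        1 for c, r in zip(counts, refs) if math.isfinite(c) and c > r.high
    )
    return calls >= min_agree


def classify_obesity(
    weight: float, ref: ControlReference, adiposity_flag: bool, k_sd: float = 1.0
) -> bool:
    """Obesity requires increased abdominal adiposity AND increased body weight.

    The weight criterion is weight > control mean + ``k_sd`` SD (strict).
    """
    return bool(adiposity_flag) and math.isfinite(weight) and weight > ref.mean + k_sd * ref.sd


def control_references(cohort: CohortTable) -> dict:
    """Per-(generation, sex) control references for every measured endpoint.

    Returns {(generation, sex): {endpoint: ControlReference}} computed from
    the cohort's own control lineage; lesion endpoints get one reference per
    observer (keys like ``testis_lesions_obs1``).
    """
    df = cohort.animals
    refs: dict = {}
    scalar_endpoints = ["puberty_day", "follicle_count", "cyst_count", "body_weight"]
    lesion_cols = [
        f"{organ}_lesions_obs{o}" for organ in LESION_ORGANS for o in range(1, N_OBSERVERS + 1)
    ]
    for (gen, sex), grp in df.groupby(["generation", "sex"], sort=False):
        stratum_refs: dict[str, ControlReference] = {}
        ctrl = grp[grp["lineage"] == "control"]
        for col in scalar_endpoints + lesion_cols:
            if col not in grp.columns:
                continue
            if grp[col].notna().sum() == 0:
                continue  # endpoint never measured in this stratum
            vals = ctrl[col].dropna()
            if len(vals) < 2:
                raise ValueError(
                    f"missing control animals for {col!r} in stratum ({gen}, {sex})"
                )
            stratum_refs[col] = control_reference(vals, endpoint=col)
        refs[(gen, sex)] = stratum_refs
    return refs


@dataclass
class DiseaseMatrix:
    """Animals x diseases grid of present/absent/not_determined calls.

    ``statuses`` is indexed by animal_id with one column per disease;
    ``meta`` carries lineage/generation/sex/litter; ``details`` holds the
    early-vs-delayed puberty annotation.
    """

    statuses: pd.DataFrame
    meta: pd.DataFrame
    details: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_diseases(self) -> pd.Series:
        """Per-animal count of present calls."""
        return (self.statuses == PRESENT).sum(axis=1).rename("n_diseases")


def _status(flag: bool) -> str:
    return PRESENT if flag else ABSENT


def build_disease_matrix(
    cohort: CohortTable,
    refs: dict | None = None,
    k_sd_obesity: float = 1.0,
    min_agree: int = 2,
) -> DiseaseMatrix:
    """Apply every classifier to a cohort and assemble the disease matrix.

    References default to the cohort's own control lineage, stratified by
    generation and sex. Endpoints missing for an animal yield
    not_determined; tumor status passes through as recorded.
    """
    if refs is None:
        refs = control_references(cohort)
    df = cohort.animals
    rows = []
    detail_rows = []
    for _, a in df.iterrows():
        stratum = refs.get((a["generation"], a["sex"]), {})
        rec: dict = {"animal_id": a["animal_id"]}
        det: dict = {"animal_id": a["animal_id"], "puberty": ND}

        ref = stratum.get("puberty_day")
        if ref is None or not math.isfinite(a.get("puberty_day", float("nan"))):
            rec["pubertal_abnormality"] = ND
        else:
            cls = classify_puberty(float(a["puberty_day"]), ref)
            rec["pubertal_abnormality"] = _status(cls in ("early", "delayed"))
            det["puberty"] = cls

        ref = stratum.get("follicle_count")
        v = a.get("follicle_count", float("nan"))
        if ref is None or not math.isfinite(v):
            rec["follicle_loss"] = ND
        else:
            rec["follicle_loss"] = _status(classify_follicle_loss(float(v), ref))

        ref = stratum.get("cyst_count")
        v = a.get("cyst_count", float("nan"))
        if ref is None or not math.isfinite(v):
            rec["polycystic_ovary"] = ND
        else:
            rec["polycystic_ovary"] = _status(classify_polycystic(float(v), ref))

        for organ in LESION_ORGANS:
            disease = f"{organ}_disease"
            cols = [f"{organ}_lesions_obs{o}" for o in range(1, N_OBSERVERS + 1)]
            obs_refs = [stratum.get(c) for c in cols]
            counts = [a.get(c, float("nan")) for c in cols]
            if any(r is None for r in obs_refs) or not all(
                math.isfinite(float(c)) for c in counts
            ):
                rec[disease] = ND
            else:
                rec[disease] = _status(
                    consensus_histopathology(
                        [float(c) for c in counts], obs_refs, min_agree=min_agree
                    )
                )

        ref = stratum.get("body_weight")
        v = a.get("body_weight", float("nan"))
        adip = a.get("adiposity_flag")
        if ref is None or not math.isfinite(v) or adip is None or (
            isinstance(adip, float) and math.isnan(adip)
        ):
            rec["obesity"] = ND
        else:
            rec["obesity"] = _status(
                classify_obesity(float(v), ref, bool(adip), k_sd=k_sd_obesity)
            )

        tumor = a.get("tumor_status", ND)
        rec["tumor"] = tumor if tumor in (PRESENT, ABSENT) else ND

        rows.append(rec)
        detail_rows.append(det)

    statuses = pd.DataFrame(rows).set_index("animal_id")[list(DISEASES)]
    meta = df.set_index("animal_id")[["lineage", "generation", "sex", "litter_id"]]
    details = pd.DataFrame(detail_rows).set_index("animal_id")
    return DiseaseMatrix(statuses=statuses, meta=meta, details=details)
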