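"""Synthetic data generators for the array and cohort arms of the pipeline.

Real MeDIP-chip raw data and necropsy tables for this study design are not
publicly deposited, so every downstream stage is exercised against simulated
inputs with known ground truth: a promoter tiling-array design, paired
two-channel hybridizations with spiked differential-methylation regions, and
animal cohorts with known injected abnormalities.

The defaults mirror the study conditions: a promoter array covering
3,880 bp upstream to 970 bp downstream of each TSS with 50-75-mer probes at
100 bp spacing (the full array scans 15,287 promoters; a desk-scale subset
is the default elsewhere), three paired treatment-vs-control hybridizations
of pooled sperm DNA (three animals per pool), and rat cohorts of control,
"plastics" and "lower dose plastics" lineages in generations F1 and F3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ArrayDesign",
    "Spike",
    "SpikePlan",
    "HybridizationSet",
    "CohortTable",
    "LineageEffect",
    "generate_array_design",
    "simulate_hybridizations",
    "simulate_cohort",
    "DEFAULT_CONTROL_PARAMS",
    "DEFAULT_EFFECTS",
    "LINEAGES",
    "GENERATIONS",
    "SEXES",
    "LESION_ORGANS",
    "N_OBSERVERS",
]

# Full-array geometry (Rat DNA Methylation promoter tiling design).
FULL_N_PROMOTERS = 15287
DEFAULT_UPSTREAM = 3880
DEFAULT_DOWNSTREAM = 970
DEFAULT_SPACING = 100
DEFAULT_PROBE_LEN_RANGE = (50, 75)

LINEAGES = ("control", "plastics", "lower_dose_plastics")
GENERATIONS = ("F1", "F3")
SEXES = ("female", "male")
LESION_ORGANS = ("testis", "prostate", "kidney")
N_OBSERVERS = 3


@dataclass(frozen=True)
class ArrayDesign:
    """Probe coordinates grouped into promoter regions.

    ``probes``: probe_id, chrom, start, end, promoter_id, gene_id
    (0-based half-open genomic coordinates).
    ``promoters``: promoter_id, chrom, tss, strand, region_start,
    region_end, gene_id.
    """

    probes: pd.DataFrame
    promoters: pd.DataFrame

    def validate(self) -> None:
        lengths = self.probes["end"] - self.probes["start"]
        if (lengths < 1).any():
            raise ValueError("probe with non-positive length")
        if (self.probes["start"] < 0).any():
            raise ValueError("negative probe coordinate")
        reg = self.promoters.set_index("promoter_id")
        joined = self.probes.join(reg, on="promoter_id", rsuffix="_prom")
        inside = (joined["start"] >= joined["region_start"]) & (
            joined["end"] <= joined["region_end"]
        )
        if not inside.all():
            bad = self.probes.loc[~inside, "probe_id"].iloc[0]
            raise ValueError(f"probe {bad} outside its promoter region")

    @property
    def n_promoters(self) -> int:
        return len(self.promoters)


@dataclass(frozen=True)
class Spike:
    """One injected differential-methylation effect (ground truth)."""

    promoter_id: str
    span_start: int
    span_end: int
    delta_m: float
    label: str


@dataclass(frozen=True)
class SpikePlan:
    spikes: tuple[Spike, ...] = ()

    def validate(self, design: ArrayDesign) -> None:
        labels = [s.label for s in self.spikes]
        if len(labels) != len(set(labels)):
            raise ValueError("spike labels must be unique")
        reg = design.promoters.set_index("promoter_id")
        for s in self.spikes:
            if s.promoter_id not in reg.index:
                raise ValueError(f"spike {s.label}: unknown promoter {s.promoter_id}")
            row = reg.loc[s.promoter_id]
            if not (row["region_start"] <= s.span_start < s.span_end <= row["region_end"]):
                raise ValueError(f"spike {s.label}: span outside promoter region")
            if s.delta_m == 0:
                raise ValueError(f"spike {s.label}: delta_m must be nonzero")

    @property
    def promoter_ids(self) -> set[str]:
        return {s.promoter_id for s in self.spikes}


@dataclass
class HybridizationSet:
    """N paired two-channel tables plus the ground truth that produced them.

    Each comparison is a DataFrame (probe_id, cy5, cy3) of strictly positive
    linear-scale intensities: cy5 carries the treatment pool, cy3 the
    control pool.
    """

    comparisons: dict[str, pd.DataFrame]
    spike_plan: SpikePlan
    metadata: dict = field(default_factory=dict)

    @property
    def comparison_ids(self) -> list[str]:
        return list(self.comparisons)


@dataclass
class CohortTable:
    """One record per animal plus the injected ground-truth abnormalities.

    ``animals`` columns: animal_id, lineage, generation, sex, litter_id,
    puberty_day, follicle_count, cyst_count, body_weight, adiposity_flag,
    {organ}_lesions_obs{1..3}, tumor_status. Endpoints not applicable to a
    sex (ovarian counts in males, testis/prostate lesions in females) are
    NaN and become "not determined" downstream.
    """

    animals: pd.DataFrame
    truth: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def _check_positive(name: str, value) -> None:
    if value is None or value <= 0:
        raise ValueError(f"{name} must be positive, got {value!r}")


def generate_array_design(
    n_promoters: int = 300,
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
    spacing: int = DEFAULT_SPACING,
    probe_len_range: tuple[int, int] = DEFAULT_PROBE_LEN_RANGE,
    n_chromosomes: int = 21,
    seed: int = 0,
    jitter: int = 0,
) -> ArrayDesign:
    """Generate a promoter tiling-array design.

    Promoter regions span ``[tss - upstream, tss + downstream]`` in
    transcription orientation (the genomic interval is mirrored on the minus
    strand); probes sit on a deterministic lattice at ``spacing`` with
    lengths drawn uniformly from ``probe_len_range``. ``jitter`` (bp)
    optionally perturbs lattice starts.
    """
    _check_positive("n_promoters", n_promoters)
    _check_positive("upstream", upstream)
    _check_positive("downstream", downstream)
    _check_positive("spacing", spacing)
    lo, hi = probe_len_range
    if not (0 < lo <= hi):
        raise ValueError(f"invalid probe_len_range {probe_len_range!r}")
    _check_positive("n_chromosomes", n_chromosomes)
    if jitter < 0 or jitter >= spacing:
        raise ValueError("jitter must be in [0, spacing)")

    rng = np.random.default_rng(seed)
    region_len = upstream + downstream

    prom_rows = []
    probe_rows = []
    # Sequential TSS placement per chromosome keeps promoters non-overlapping.
    next_pos = np.full(n_chromosomes, 10_000 + region_len)
    for k in range(n_promoters):
        ci = k % n_chromosomes
        chrom = f"chr{ci + 1}"
        gap = int(rng.integers(5_000, 50_000))
        tss = int(next_pos[ci])
        next_pos[ci] = tss + region_len + gap
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            region_start, region_end = tss - upstream, tss + downstream
        else:
            region_start, region_end = tss - downstream, tss + upstream
        pid = f"prom{k:05d}"
        gid = f"gene{k:05d}"
        prom_rows.append((pid, chrom, tss, strand, region_start, region_end, gid))

        n_slots = (region_end - region_start) // spacing
        starts = region_start + spacing * np.arange(n_slots)
        if jitter:
            starts = starts + rng.integers(-jitter, jitter + 1, size=n_slots)
        lens = rng.integers(lo, hi + 1, size=n_slots)
        keep = starts + lens <= region_end
        starts, lens = starts[keep], lens[keep]
        for i, (s, ln) in enumerate(zip(starts, lens)):
            probe_rows.append((f"{pid}_p{i:03d}", chrom, int(s), int(s + ln), pid, gid))

    promoters = pd.DataFrame(
        prom_rows,
        columns=["promoter_id", "chrom", "tss", "strand", "region_start", "region_end", "gene_id"],
    )
    probes = pd.DataFrame(
        probe_rows, columns=["probe_id", "chrom", "start", "end", "promoter_id", "gene_id"]
    )
    design = ArrayDesign(probes=probes, promoters=promoters)
    design.validate()
    return design


def simulate_hybridizations(
    design: ArrayDesign,
    spike_plan: SpikePlan | None = None,
    n_comparisons: int = 3,
    baseline_log_mean: float = 10.0,
    noise_sd: float = 0.2,
    dye_bias: float = 0.0,
    pool_sd: float = 0.0,
    seed: int = 0,
) -> HybridizationSet:
    """Simulate paired two-channel hybridizations with known spiked DMRs.

    The intensity model is log-normal on the log2 scale: for probe i in
    comparison c,

        log2 cy5 = A0 + (m_i + u_c)/2 + e5,   log2 cy3 = A0 - (m_i + u_c)/2 + e3

    with ``A0 = baseline_log_mean``, ``m_i = dye_bias + delta_m`` for probes
    under a spike (``dye_bias`` alone elsewhere), an optional per-comparison
    pool effect ``u_c ~ N(0, pool_sd)``, and independent channel noise
    ``e ~ N(0, noise_sd)``. The expected M after the MA transform is
    therefore ``m_i`` and the M noise SD is ``noise_sd * sqrt(2)``;
    intensities are strictly positive by construction. A probe is "under" a
    spike when its start lies in ``[span_start, span_end)``.
    """
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    if noise_sd < 0 or pool_sd < 0:
        raise ValueError("noise_sd and pool_sd must be >= 0")
    if len(design.probes) == 0:
        raise ValueError("design has no probes")
    spike_plan = spike_plan or SpikePlan()
    spike_plan.validate(design)

    probes = design.probes
    m_true = np.full(len(probes), float(dye_bias))
    for s in spike_plan.spikes:
        under = (
            (probes["promoter_id"] == s.promoter_id)
            & (probes["start"] >= s.span_start)
            & (probes["start"] < s.span_end)
        ).to_numpy()
        m_true[under] += s.delta_m

    rng = np.random.default_rng(seed)
    comparisons: dict[str, pd.DataFrame] = {}
    pool_ids = []
    for c in range(n_comparisons):
        cid = f"c{c + 1}"
        u = rng.normal(0.0, pool_sd) if pool_sd > 0 else 0.0
        half = (m_true + u) / 2.0
        log_cy5 = baseline_log_mean + half + rng.normal(0.0, noise_sd, len(probes))
        log_cy3 = baseline_log_mean - half + rng.normal(0.0, noise_sd, len(probes))
        comparisons[cid] = pd.DataFrame(
            {
                "probe_id": probes["probe_id"].to_numpy(),
                "cy5": np.exp2(log_cy5),
                "cy3": np.exp2(log_cy3),
            }
        )
        pool_ids.append({"comparison": cid, "treatment_pool": f"P{c + 1}", "control_pool": f"C{c + 1}"})

    return HybridizationSet(
        comparisons=comparisons,
        spike_plan=spike_plan,
        metadata={
            "seed": seed,
            "pools": pool_ids,
            "animals_per_pool": 3,
            "baseline_log_mean": baseline_log_mean,
            "noise_sd": noise_sd,
            "dye_bias": dye_bias,
            "pool_sd": pool_sd,
        },
    )


@dataclass(frozen=True)
class LineageEffect:
    """Treatment effects applied to one lineage.

    ``shifts`` maps endpoint -> shift in units of the control SD, applied to
    affected animals; ``affected_prob`` maps endpoint -> probability an
    animal carries the shift (default 1.0). ``lesion_shift_sd`` shifts every
    observer's lesion count for the named organs. Binary conditions are
    controlled by ``adiposity_prob`` and ``tumor_prob``.
    """

    shifts: dict = field(default_factory=dict)
    affected_prob: dict = field(default_factory=dict)
    lesion_shift_sd: dict = field(default_factory=dict)
    lesion_affected_prob: dict = field(default_factory=dict)
    adiposity_prob: float = 0.0
    tumor_prob: float = 0.0


# Control-lineage endpoint distributions (mean, SD), per sex where the
# endpoint is sex-specific. Units: puberty in postnatal days (vaginal
# opening / balano-preputial separation), follicle and cyst counts per ovary
# section (mean of three sections), body weight in grams at one year,
# lesion counts per examined tissue section.
DEFAULT_CONTROL_PARAMS: dict = {
    "puberty_day": {"mean": {"female": 34.0, "male": 43.0}, "sd": 2.0},
    "follicle_count": {"mean": 45.0, "sd": 8.0, "sexes": ("female",)},
    "cyst_count": {"mean": 2.0, "sd": 1.2, "sexes": ("female",)},
    "body_weight": {"mean": {"female": 283.0, "male": 509.0}, "sd": {"female": 35.0, "male": 32.0}},
    "testis_lesions": {"mean": 1.5, "sd": 1.0, "sexes": ("male",)},
    "prostate_lesions": {"mean": 1.5, "sd": 1.0, "sexes": ("male",)},
    "kidney_lesions": {"mean": 1.5, "sd": 1.0},
}

# Lineage effects emulating the reported direction and magnitude of the
# study's findings: severe primordial-follicle loss and cyst increase in
# treated females, delayed male / early female puberty shifts, lesion
# increases in treated tissues, adiposity mostly in treated F3 animals.
DEFAULT_EFFECTS: dict = {
    "control": LineageEffect(adiposity_prob=0.02, tumor_prob=0.05),
    "plastics": LineageEffect(
        shifts={"puberty_day": 3.0, "follicle_count": -6.0, "cyst_count": 6.0, "body_weight": 1.5},
        affected_prob={"puberty_day": 0.5, "follicle_count": 0.9, "cyst_count": 0.9, "body_weight": 0.25},
        lesion_shift_sd={"testis": 4.0, "prostate": 3.0, "kidney": 3.0},
        lesion_affected_prob={"testis": 0.35, "prostate": 0.3, "kidney": 0.3},
        adiposity_prob=0.25,
        tumor_prob=0.05,
    ),
    "lower_dose_plastics": LineageEffect(
        shifts={"puberty_day": 3.0, "follicle_count": -6.0, "cyst_count": 6.0, "body_weight": 1.5},
        affected_prob={"puberty_day": 0.35, "follicle_count": 0.85, "cyst_count": 0.9, "body_weight": 0.3},
        lesion_shift_sd={"testis": 4.0, "prostate": 3.0, "kidney": 3.0},
        lesion_affected_prob={"testis": 0.4, "prostate": 0.2, "kidney": 0.25},
        adiposity_prob=0.3,
        tumor_prob=0.05,
    ),
}


def _param_for(spec: dict, key: str, sex: str) -> float:
    v = spec[key]
    return float(v[sex]) if isinstance(v, dict) else float(v)


def simulate_cohort(
    n_per_cell: int = 15,
    control_params: dict | None = None,
    effect_params: dict | None = None,
    litters_per_cell: int = 4,
    nd_prob: float = 0.0,
    seed: int = 0,
) -> CohortTable:
    """Simulate an animal cohort with known abnormality ground truth.

    One cell is a lineage x generation x sex stratum with ``n_per_cell``
    animals assigned round-robin to ``litters_per_cell`` litters. Control
    animals draw every endpoint from ``control_params``; treated animals are
    "affected" per endpoint with the lineage's ``affected_prob`` and then
    shifted by ``shifts`` (in control-SD units). ``nd_prob`` blanks an
    endpoint to not-determined at random, emulating incomplete necropsy
    evaluation. Injected abnormalities are returned in ``truth``.
    """
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be >= 1")
    _check_positive("litters_per_cell", litters_per_cell)
    control_params = control_params if control_params is not None else DEFAULT_CONTROL_PARAMS
    effect_params = effect_params if effect_params is not None else DEFAULT_EFFECTS
    for ep in control_params.values():
        sd = ep["sd"]
        sds = sd.values() if isinstance(sd, dict) else [sd]
        if any(s < 0 for s in sds):
            raise ValueError("endpoint sd must be >= 0")
    unknown = set(effect_params) - set(LINEAGES)
    if unknown:
        raise ValueError(f"unknown lineage(s) in effect_params: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    rows = []
    truth_rows = []
    counter = 0
    for lineage in LINEAGES:
        eff = effect_params.get(lineage, LineageEffect())
        prefix = {"control": "C", "plastics": "P", "lower_dose_plastics": "LP"}[lineage]
        for gen in GENERATIONS:
            for sex in SEXES:
                for i in range(n_per_cell):
                    counter += 1
                    aid = f"{prefix}-{gen}-{sex[0].upper()}{i + 1:03d}"
                    litter = f"{prefix}-{gen}-L{(i % litters_per_cell) + 1}"
                    rec = {
                        "animal_id": aid,
                        "lineage": lineage,
                        "generation": gen,
                        "sex": sex,
                        "litter_id": litter,
                    }
                    tru = {"animal_id": aid}
                    for name, spec in control_params.items():
                        sexes = spec.get("sexes", SEXES)
                        if sex not in sexes:
                            if not name.endswith("_lesions"):
                                rec[name] = np.nan
                            continue
                        mean = _param_for(spec, "mean", sex)
                        sd = _param_for(spec, "sd", sex)
                        shift = eff.shifts.get(name, 0.0)
                        p_aff = eff.affected_prob.get(name, 1.0)
                        affected = bool(shift) and rng.random() < p_aff
                        value = rng.normal(mean + (shift * sd if affected else 0.0), sd)
                        tru[f"affected_{name}"] = affected
                        if name.endswith("_lesions"):
                            organ = name[: -len("_lesions")]
                            o_shift = eff.lesion_shift_sd.get(organ, 0.0)
                            o_aff = bool(o_shift) and rng.random() < eff.lesion_affected_prob.get(organ, 1.0)
                            tru[f"affected_{name}"] = o_aff
                            for obs in range(1, N_OBSERVERS + 1):
                                v = rng.normal(mean + (o_shift * sd if o_aff else 0.0), sd)
                                rec[f"{organ}_lesions_obs{obs}"] = max(v, 0.0)
                        elif name in ("follicle_count", "cyst_count"):
                            rec[name] = max(value, 0.0)
                        elif name == "body_weight":
                            rec[name] = max(value, 1.0)
                        else:
                            rec[name] = value
                    adip = rng.random() < eff.adiposity_prob
                    rec["adiposity_flag"] = adip
                    tru["affected_adiposity"] = adip
                    if rng.random() < eff.tumor_prob:
                        rec["tumor_status"] = "present"
                        tru["affected_tumor"] = True
                    else:
                        rec["tumor_status"] = "absent"
                        tru["affected_tumor"] = False
                    if nd_prob > 0:
                        for col in list(rec):
                            if col in ("animal_id", "lineage", "generation", "sex", "litter_id"):
                                continue
                            if rng.random() < nd_prob:
                                rec[col] = "not_determined" if col == "tumor_status" else np.nan
                    rows.append(rec)
                    truth_rows.append(tru)

    animals = pd.DataFrame(rows)
    # Lesion columns exist even if a sex never got them.
    for organ in LESION_ORGANS:
        for obs in range(1, N_OBSERVERS + 1):
            col = f"{organ}_lesions_obs{obs}"
            if col not in animals.columns:
                animals[col] = np.nan
    truth = pd.DataFrame(truth_rows).set_index("animal_id")
    return CohortTable(
        animals=animals,
        truth=truth,
        metadata={"seed": seed, "n_per_cell": n_per_cell, "litters_per_cell": litters_per_cell},
    )
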