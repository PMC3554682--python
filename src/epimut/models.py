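"""Model/Results objects tying the pipeline stages together.

:class:`DMRModel` fits the window-median Z statistic to a set of paired
two-channel hybridizations and returns :class:`DMRResults` carrying window
statistics, called regions and summaries. :class:`CohortDiseaseModel`
applies the control-referenced classification rules to an animal cohort and
returns :class:`CohortDiseaseResults` with the disease matrix, incidence
table and treated-vs-control tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import io as eio
from .incidence import (
    build_incidence,
    litter_representation_check,
    logistic_incidence_test,
    stars,
)
from .medip import (
    MAValues,
    WindowConfig,
    call_dmrs,
    normalize_ma,
    score_windows,
    summarize_by_chromosome,
    summarize_categories,
    window_statistics,
)
from .phenotype import DiseaseMatrix, build_disease_matrix, control_references
from .simulate import ArrayDesign, CohortTable, HybridizationSet

__all__ = ["DMRModel", "DMRResults", "CohortDiseaseModel", "CohortDiseaseResults"]


class DMRModel:
    """Differential-methylation-region model for paired MeDIP hybridizations.

    Parameters
    ----------
    design : ArrayDesign
        Probe and promoter coordinates of the tiling array.
    comparisons : HybridizationSet or dict[str, DataFrame]
        Paired channel tables (probe_id, cy5, cy3), one per comparison.
    config : WindowConfig
        Window construction, normalization and significance settings.
    """

    def __init__(self, design: ArrayDesign, comparisons, config: WindowConfig = WindowConfig()):
        self.design = design
        if isinstance(comparisons, HybridizationSet):
            self.channel_tables = comparisons.comparisons
        else:
            self.channel_tables = dict(comparisons)
        if not self.channel_tables:
            raise ValueError("no comparisons given")
        self.config = config

    @classmethod
    def from_files(cls, design_path, comparison_paths, config: WindowConfig = WindowConfig()):
        design = eio.read_design(design_path)
        tables = eio.read_comparisons(comparison_paths)
        return cls(design, tables, config)

    def fit(self) -> "DMRResults":
        """Run MA transform -> normalization -> windows -> scoring -> calling."""
        from .medip import compute_ma

        ma = MAValues({cid: compute_ma(t) for cid, t in self.channel_tables.items()})
        ma = normalize_ma(ma, method=self.config.normalization)
        windows = window_statistics(ma, self.design, self.config)
        scored = score_windows(windows, self.config)
        dmrs = call_dmrs(scored, self.config)
        return DMRResults(model=self, ma=ma, window_stats=scored, dmrs=dmrs)


@dataclass
class DMRResults:
    """Fitted DMR-calling results."""

    model: DMRModel
    ma: MAValues
    window_stats: pd.DataFrame
    dmrs: pd.DataFrame

    @property
    def n_dmrs(self) -> int:
        return len(self.dmrs)

    @property
    def dmr_promoters(self) -> list[str]:
        """Promoters carrying at least one called region."""
        return sorted(self.dmrs["promoter_id"].unique())

    def by_chromosome(self) -> pd.DataFrame:
        return summarize_by_chromosome(self.dmrs)

    def by_category(self, gene_categories: dict) -> pd.DataFrame:
        return summarize_categories(self.dmrs, gene_categories)

    def to_bed(self, path) -> None:
        eio.write_bed(self.dmrs, path)

    def to_table(self, path, gene_categories: dict | None = None) -> None:
        eio.write_dmr_table(self.dmrs, path, gene_categories)

    def summary(self) -> str:
        cfg = self.model.config
        n_comp = self.window_stats["comparison_id"].nunique()
        n_windows = len(self.window_stats) // max(n_comp, 1)
        lines = [
            "Differential DNA methylation region (DMR) calling",
            "=" * 50,
            f"promoters on array:        {self.model.design.n_promoters}",
            f"paired comparisons:        {n_comp}",
            f"window: {cfg.window_bp} bp, >= {cfg.min_probes} probes ({cfg.method})",
            f"alpha per comparison:      {cfg.alpha}"
            + (" (two-sided)" if cfg.two_sided else " (one-sided)"),
            f"windows scored:            {n_windows}",
            f"DMRs called:               {self.n_dmrs}",
            f"promoters with a DMR:      {len(self.dmr_promoters)}",
        ]
        bych = self.by_chromosome()
        if not bych.empty:
            lines.append("per chromosome: " + ", ".join(
                f"{r.chrom}:{r.n_dmrs}" for r in bych.itertuples()
            ))
        return "\n".join(lines)

    def plot_chromosome_counts(self, ax=None):
        """Bar plot of DMR counts per chromosome."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 3))
        bych = self.by_chromosome()
        ax.bar(bych["chrom"], bych["n_dmrs"], color="0.3")
        ax.set_ylabel("DMRs")
        ax.set_xlabel("chromosome")
        ax.tick_params(axis="x", rotation=90)
        return ax


class CohortDiseaseModel:
    """Disease classification and incidence model for an animal cohort.

    Control references (mean ± 2 SD per endpoint) come from the cohort's
    own control lineage, stratified by generation and sex.
    """

    def __init__(self, cohort: CohortTable, k_sd_obesity: float = 1.0, min_agree: int = 2):
        self.cohort = cohort
        self.k_sd_obesity = k_sd_obesity
        self.min_agree = min_agree

    @classmethod
    def from_csv(cls, path, **kwargs):
        return cls(eio.read_cohort(path), **kwargs)

    def fit(self) -> "CohortDiseaseResults":
        refs = control_references(self.cohort)
        matrix = build_disease_matrix(
            self.cohort, refs=refs, k_sd_obesity=self.k_sd_obesity, min_agree=self.min_agree
        )
        incidence = build_incidence(matrix)
        tests = self._incidence_tests(incidence)
        return CohortDiseaseResults(
            model=self, references=refs, matrix=matrix, incidence=incidence, tests=tests
        )

    @staticmethod
    def _incidence_tests(incidence: pd.DataFrame) -> pd.DataFrame:
        """Per stratum and disease, treated lineage vs control logistic test."""
        rows = []
        key = ["generation", "sex", "disease"]
        ctrl = incidence[incidence["lineage"] == "control"].set_index(key)
        for lin in incidence["lineage"].unique():
            if lin == "control":
                continue
            sub = incidence[incidence["lineage"] == lin]
            for _, r in sub.iterrows():
                k = (r["generation"], r["sex"], r["disease"])
                if k not in ctrl.index:
                    continue
                c = ctrl.loc[k]
                res = logistic_incidence_test(
                    int(r["affected"]), int(r["evaluated"]),
                    int(c["affected"]), int(c["evaluated"]),
                    label=f"{lin} vs control / {k[0]} {k[1]} / {k[2]}",
                )
                rows.append(
                    (
                        lin, r["generation"], r["sex"], r["disease"],
                        int(r["affected"]), int(r["evaluated"]),
                        int(c["affected"]), int(c["evaluated"]),
                        res.estimate, res.p, res.method, res.flag, stars(res.p),
                    )
                )
        return pd.DataFrame(
            rows,
            columns=[
                "lineage", "generation", "sex", "disease",
                "affected", "evaluated", "control_affected", "control_evaluated",
                "odds_ratio", "p", "method", "flag", "stars",
            ],
        )


@dataclass
class CohortDiseaseResults:
    """Fitted cohort classification results."""

    model: CohortDiseaseModel
    references: dict
    matrix: DiseaseMatrix
    incidence: pd.DataFrame
    tests: pd.DataFrame
    _litter: pd.DataFrame | None = field(default=None, repr=False)

    def litter_check(self) -> pd.DataFrame:
        if self._litter is None:
            self._litter = litter_representation_check(self.matrix, self.model.cohort)
        return self._litter

    def to_matrix_csv(self, path) -> None:
        eio.write_disease_matrix(self.matrix, path)

    def to_incidence_csv(self, path) -> None:
        self.incidence.to_csv(path, index=False)

    def summary(self) -> str:
        """Star-annotated incidence summary (a/n and percent per stratum)."""
        lines = [
            "Transgenerational disease incidence",
            "=" * 60,
            f"animals: {len(self.matrix.statuses)}   "
            f"diseases scored: {self.matrix.statuses.shape[1]} (+ total/multiple)",
            "",
            f"{'lineage':<22}{'gen':<5}{'sex':<8}{'disease':<22}{'a/n':>8}{'%':>5}  sig",
            "-" * 75,
        ]
        tests = self.tests.set_index(["lineage", "generation", "sex", "disease"])
        for _, r in self.incidence.iterrows():
            k = (r["lineage"], r["generation"], r["sex"], r["disease"])
            star = tests.loc[k, "stars"] if k in tests.index else ""
            an = f"{r['affected']}/{r['evaluated']}"
            lines.append(
                f"{r['lineage']:<22}{r['generation']:<5}{r['sex']:<8}{r['disease']:<22}"
                f"{an:>8}{r['percent']:>5}  {star}"
            )
        return "\n".join(lines)

    def plot_incidence(self, disease: str, ax=None):
        """Grouped bar plot of percent incidence for one disease."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3))
        sub = self.incidence[self.incidence["disease"] == disease]
        labels = [f"{r.lineage}\n{r.generation} {r.sex}" for r in sub.itertuples()]
        ax.bar(range(len(sub)), sub["percent"], color="0.4")
        ax.set_xticks(range(len(sub)), labels, fontsize=6, rotation=45, ha="right")
        ax.set_ylabel("% affected")
        ax.set_title(disease)
        for i, r in enumerate(sub.itertuples()):
            ax.text(i, r.percent, f"{r.affected}/{r.evaluated}", ha="center", fontsize=6)
        return ax
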