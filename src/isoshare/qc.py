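"""Staged sample/variant quality control for exome-array genotype matrices.

The pipeline mirrors the standard staged QC of array-genotyped isolate
cohorts: a loose prefilter on call rate, sample-level call-rate and
heterozygosity-outlier exclusion (stratified at MAF 1%), variant-level
call-rate and Hardy-Weinberg filters, a tighter final variant call-rate
cut, removal of samples carrying an excess of singleton alleles, and a
final Hardy-Weinberg pass.  Filters only drop rows/columns; genotype values
are never altered.  All comparisons are strict.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix
from .variant_stats import VariantCounts, hwe_exact_test


@dataclass
class QCThresholds:
    prefilter_call_rate: float = 0.90
    sample_call_rate: float = 0.98
    het_outlier_sd: float = 3.0
    het_maf_split: float = 0.01
    variant_call_rate: float = 0.95
    hwe_p: float = 1e-4
    final_variant_call_rate: float = 0.99
    singleton_sample_limit: int = 100

    def __post_init__(self) -> None:
        for name in (
            "prefilter_call_rate",
            "sample_call_rate",
            "variant_call_rate",
            "final_variant_call_rate",
            "het_maf_split",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 < self.hwe_p < 1:
            raise ValueError("hwe_p must lie in (0, 1)")


@dataclass
class QCStage:
    stage: str
    axis: str  # "samples" | "variants"
    removed: list
    n_before: int
    n_after: int


@dataclass
class QCReport:
    stages: list[QCStage] = field(default_factory=list)

    def add(self, stage: str, axis: str, removed: list, n_before: int) -> None:
        self.stages.append(QCStage(stage, axis, list(removed), n_before, n_before - len(removed)))

    def removed_ids(self, axis: str | None = None) -> list:
        out = []
        for s in self.stages:
            if axis is None or s.axis == axis:
                out.extend(s.removed)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": s.stage,
                    "axis": s.axis,
                    "n_before": s.n_before,
                    "n_removed": len(s.removed),
                    "n_after": s.n_after,
                }
                for s in self.stages
            ]
        )

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        lines = []
        for s in self.stages:
            lines.append(
                f"{s.stage} [{s.axis}]: {s.n_before} -> {s.n_after} "
                f"({len(s.removed)} removed)"
            )
        return "\n".join(lines)


def call_rate_filter(
    g: GenotypeMatrix, axis: str, threshold: float, report: QCReport | None = None,
    stage: str = "call_rate",
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop samples or variants whose call rate is strictly below threshold."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    report = report if report is not None else QCReport()
    rates = g.call_rate(axis)
    keep = rates >= threshold
    if axis == "samples":
        removed = [g.samples[i] for i in np.flatnonzero(~keep)]
        report.add(stage, axis, removed, g.n_samples)
        return g.take_samples(keep), report
    removed = g.variants["id"].to_numpy()[~keep].tolist()
    report.add(stage, axis, removed, g.n_variants)
    return g.take_variants(keep), report


def heterozygosity_outliers(
    g: GenotypeMatrix, maf_split: float = 0.01, sd_mult: float = 3.0
) -> list[str]:
    """Samples whose heterozygous-call fraction is an outlier in either MAF
    stratum.

    The het fraction is computed per sample separately over rare
    (MAF < ``maf_split``) and common (MAF >= ``maf_split``) variants; a sample
    is flagged when it lies more than ``sd_mult`` SDs from the cohort mean in
    either stratum.  An empty stratum is skipped with a warning.
    """
    if g.n_samples < 3:
        raise ValueError("need at least 3 samples for outlier detection")
    maf = g.maf()
    flagged: set[str] = set()
    for name, mask in (("rare", maf < maf_split), ("common", maf >= maf_split)):
        poly = mask & (maf > 0)
        if poly.sum() == 0:
            warnings.warn(f"no polymorphic variants in {name} MAF stratum; skipped")
            continue
        sub = g.genotypes[:, poly]
        called = sub != MISSING
        n_called = called.sum(axis=1)
        with np.errstate(invalid="ignore"):
            het = (sub == 1).sum(axis=1) / np.maximum(n_called, 1)
        het = np.where(n_called > 0, het, np.nan)
        ok = ~np.isnan(het)
        mean = het[ok].mean()
        sd = het[ok].std(ddof=1)
        if sd == 0 or np.isinf(sd_mult):
            continue
        out = ok & (np.abs(het - mean) > sd_mult * sd)
        flagged.update(g.samples[i] for i in np.flatnonzero(out))
    return sorted(flagged, key=g.samples.index)


def hwe_filter(
    g: GenotypeMatrix, p_threshold: float = 1e-4, report: QCReport | None = None,
    stage: str = "hwe",
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop variants whose Hardy-Weinberg exact-test p is strictly below the
    threshold.  Monomorphic variants have p = 1 and are never removed."""
    report = report if report is not None else QCReport()
    pvals = np.empty(g.n_variants)
    for j in range(g.n_variants):
        col = g.genotypes[:, j]
        counts = VariantCounts(
            int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
        )
        pvals[j] = hwe_exact_test(counts) if counts.total > 0 else 1.0
    keep = pvals >= p_threshold
    removed = g.variants["id"].to_numpy()[~keep].tolist()
    report.add(stage, "variants", removed, g.n_variants)
    return g.take_variants(keep), report


def singleton_sample_filter(
    g: GenotypeMatrix, limit: int = 100, report: QCReport | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop samples that are the sole carrier of the minor allele at strictly
    more than ``limit`` variants."""
    report = report if report is not None else QCReport()
    geno = g.genotypes
    freq = g.alt_allele_frequency()
    singleton_counts = np.zeros(g.n_samples, dtype=int)
    for j in range(g.n_variants):
        f = freq[j]
        if np.isnan(f):
            continue
        col = geno[:, j]
        minor_is_alt = f <= 0.5
        if minor_is_alt:
            mac = int(col[col != MISSING].sum())
            carriers = np.flatnonzero((col == 1) | (col == 2))
        else:
            called = col != MISSING
            mac = int((2 - col[called]).sum())
            carriers = np.flatnonzero((col == 1) | (col == 0))
        if mac == 1 and len(carriers) == 1:
            singleton_counts[carriers[0]] += 1
    keep = singleton_counts <= limit
    removed = [g.samples[i] for i in np.flatnonzero(~keep)]
    report.add("singleton_samples", "samples", removed, g.n_samples)
    return g.take_samples(keep), report


def run_qc_pipeline(
    g: GenotypeMatrix, thresholds: QCThresholds | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Run the full staged QC pipeline and return the surviving matrix plus a
    cumulative per-stage report."""
    t = thresholds or QCThresholds()
    report = QCReport()

    g, _ = call_rate_filter(g, "samples", t.prefilter_call_rate, report, "prefilter_call_rate")
    g, _ = call_rate_filter(g, "variants", t.prefilter_call_rate, report, "prefilter_call_rate")
    g, _ = call_rate_filter(g, "samples", t.sample_call_rate, report, "sample_call_rate")

    if g.n_samples >= 3:
        het_out = heterozygosity_outliers(g, t.het_maf_split, t.het_outlier_sd)
    else:
        het_out = []
    keep = np.array([s not in set(het_out) for s in g.samples])
    report.add("het_outliers", "samples", het_out, g.n_samples)
    g = g.take_samples(keep)

    g, _ = call_rate_filter(g, "variants", t.variant_call_rate, report, "variant_call_rate")
    g, _ = hwe_filter(g, t.hwe_p, report, "hwe")
    g, _ = call_rate_filter(
        g, "variants", t.final_variant_call_rate, report, "final_variant_call_rate"
    )
    g, _ = singleton_sample_filter(g, t.singleton_sample_limit, report)
    g, _ = hwe_filter(g, t.hwe_p, report, "final_hwe")
    return g, report
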