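"""Core in-memory containers: diploid genotype matrix and genetic map.

Genotypes are stored as an ``(n_samples, n_variants)`` array of alternate-allele
dosages ``{0, 1, 2}`` with ``-1`` marking a missing call.  Coordinates are
1-based and intervals are closed, matching the convention of the analyses
built on top of these containers.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

_VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Samples-by-variants diploid genotype calls with variant metadata.

    Parameters
    ----------
    genotypes
        ``(n_samples, n_variants)`` integer array of alt-allele counts;
        ``-1`` encodes a missing genotype.
    samples
        Sample identifiers, one per row.
    variants
        Data frame with columns ``chrom, pos, id, ref, alt`` (1-based ``pos``,
        strictly increasing within a chromosome).
    """

    genotypes: np.ndarray
    samples: list[str]
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D (samples x variants) array")
        if self.genotypes.shape[0] != len(self.samples):
            raise ValueError("sample count does not match genotype rows")
        if self.genotypes.shape[1] != len(self.variants):
            raise ValueError("variant count does not match genotype columns")
        missing_cols = set(_VARIANT_COLUMNS) - set(self.variants.columns)
        if missing_cols:
            raise ValueError(f"variant table lacks columns: {sorted(missing_cols)}")
        self.variants = self.variants.reset_index(drop=True)

    # -- basic properties -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return self.variants["pos"].to_numpy()

    def called_mask(self) -> np.ndarray:
        return self.genotypes != MISSING

    def call_rate(self, axis: str) -> np.ndarray:
        """Fraction of non-missing calls per sample (``axis='samples'``) or
        per variant (``axis='variants'``)."""
        called = self.called_mask()
        if axis == "samples":
            return called.mean(axis=1)
        if axis == "variants":
            return called.mean(axis=0)
        raise ValueError("axis must be 'samples' or 'variants'")

    def alt_allele_frequency(self) -> np.ndarray:
        """Per-variant alternate-allele frequency over non-missing calls."""
        g = np.ma.masked_equal(self.genotypes, MISSING)
        n_called = (~g.mask).sum(axis=0) if g.mask is not np.ma.nomask else np.full(
            self.n_variants, self.n_samples
        )
        with np.errstate(invalid="ignore"):
            freq = g.sum(axis=0).filled(0) / (2.0 * np.maximum(n_called, 1))
        return np.where(n_called > 0, freq, np.nan)

    def maf(self) -> np.ndarray:
        f = self.alt_allele_frequency()
        return np.minimum(f, 1.0 - f)

    # -- subsetting --------------------------------------------------------

    def take_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.genotypes[index, :],
            [self.samples[i] for i in index],
            self.variants,
        )

    def take_variants(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.genotypes[:, index],
            self.samples,
            self.variants.iloc[index].reset_index(drop=True),
        )

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample: {sample_id}") from None

    # -- VCF I/O -----------------------------------------------------------

    @classmethod
    def from_vcf(cls, path: str) -> "GenotypeMatrix":
        """Read diploid GT calls from a VCF using cyvcf2."""
        from cyvcf2 import VCF

        vcf = VCF(str(path), gts012=True)
        samples = list(vcf.samples)
        rows = []
        geno_cols = []
        for rec in vcf:
            rows.append(
                (rec.CHROM, rec.POS, rec.ID or f"{rec.CHROM}:{rec.POS}", rec.REF, rec.ALT[0])
            )
            gt = rec.gt_types.astype(np.int8)  # 0/1/2, 3 = unknown
            gt[gt == 3] = MISSING
            geno_cols.append(gt)
        vcf.close()
        variants = pd.DataFrame(rows, columns=_VARIANT_COLUMNS)
        genotypes = (
            np.stack(geno_cols, axis=1) if geno_cols else np.empty((len(samples), 0), np.int8)
        )
        return cls(genotypes, samples, variants)

    def to_vcf(self, path: str, haplotypes: np.ndarray | None = None) -> None:
        """Write the matrix as an uncompressed VCF.

        If ``haplotypes`` (``(n_samples, 2, n_variants)`` 0/1 alleles) is given,
        phased ``a|b`` genotypes are written; otherwise unphased dosage calls.
        """
        import pysam

        header = pysam.VariantHeader()
        header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
        for chrom in pd.unique(self.variants["chrom"]):
            sub = self.variants[self.variants["chrom"] == chrom]
            header.contigs.add(str(chrom), length=int(sub["pos"].max()) + 1)
        for s in self.samples:
            header.add_sample(s)
        with pysam.VariantFile(str(path), "w", header=header) as out:
            for j, row in self.variants.iterrows():
                rec = out.new_record(
                    contig=str(row["chrom"]),
                    start=int(row["pos"]) - 1,
                    stop=int(row["pos"]),
                    alleles=(str(row["ref"]), str(row["alt"])),
                    id=str(row["id"]),
                )
                for i, s in enumerate(self.samples):
                    if haplotypes is not None:
                        rec.samples[s]["GT"] = (
                            int(haplotypes[i, 0, j]),
                            int(haplotypes[i, 1, j]),
                        )
                        rec.samples[s].phased = True
                    else:
                        g = int(self.genotypes[i, j])
                        if g == MISSING:
                            rec.samples[s]["GT"] = (None, None)
                        else:
                            rec.samples[s]["GT"] = (0, 0) if g == 0 else (
                                (0, 1) if g == 1 else (1, 1)
                            )
                out.write(rec)


@dataclass
class GeneticMap:
    """Monotone physical-position -> cumulative genetic position (cM) map.

    Between map points the genetic position is interpolated linearly; beyond
    the ends it is extrapolated with the terminal recombination rate.
    """

    chrom: str
    positions_bp: np.ndarray
    cumulative_cm: np.ndarray
    rates_cm_per_mb: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions_bp = np.asarray(self.positions_bp, dtype=float)
        self.cumulative_cm = np.asarray(self.cumulative_cm, dtype=float)
        if self.positions_bp.ndim != 1 or self.positions_bp.shape != self.cumulative_cm.shape:
            raise ValueError("positions and cM arrays must be 1-D and equal length")
        if len(self.positions_bp) < 2:
            raise ValueError("a genetic map needs at least two points")
        if np.any(np.diff(self.positions_bp) <= 0):
            raise ValueError("map positions must be strictly increasing")
        if np.any(np.diff(self.cumulative_cm) < 0):
            raise ValueError("cumulative cM must be non-decreasing")
        if self.rates_cm_per_mb is None:
            seg = np.diff(self.cumulative_cm) / (np.diff(self.positions_bp) / 1e6)
            self.rates_cm_per_mb = np.append(seg, seg[-1])
        else:
            self.rates_cm_per_mb = np.asarray(self.rates_cm_per_mb, dtype=float)

    @classmethod
    def uniform(cls, chrom: str, length_bp: int, cm_per_mb: float = 1.0) -> "GeneticMap":
        pos = np.array([1.0, float(length_bp)])
        cm = (pos - 1.0) / 1e6 * cm_per_mb
        return cls(chrom, pos, cm, np.array([cm_per_mb, cm_per_mb]))

    @classmethod
    def piecewise(cls, chrom: str, breakpoints_bp, rates_cm_per_mb) -> "GeneticMap":
        """Build from interval starts and per-interval rates (last rate
        extends to the final breakpoint)."""
        bp = np.asarray(breakpoints_bp, dtype=float)
        rates = np.asarray(rates_cm_per_mb, dtype=float)
        if len(rates) != len(bp) - 1:
            raise ValueError("need one rate per interval between breakpoints")
        cm = np.concatenate([[0.0], np.cumsum(np.diff(bp) / 1e6 * rates)])
        return cls(chrom, bp, cm, np.append(rates, rates[-1]))

    def cm_at(self, pos_bp) -> np.ndarray | float:
        pos = np.asarray(pos_bp, dtype=float)
        cm = np.interp(pos, self.positions_bp, self.cumulative_cm)
        # linear extrapolation with the edge rates
        lo, hi = self.positions_bp[0], self.positions_bp[-1]
        cm = np.where(
            pos < lo,
            self.cumulative_cm[0] - (lo - pos) / 1e6 * self.rates_cm_per_mb[0],
            cm,
        )
        cm = np.where(
            pos > hi,
            self.cumulative_cm[-1] + (pos - hi) / 1e6 * self.rates_cm_per_mb[-1],
            cm,
        )
        return float(cm) if np.isscalar(pos_bp) else cm

    def bp_at(self, cm) -> np.ndarray | float:
        """Inverse interpolation (flat map segments resolve to their start)."""
        c = np.asarray(cm, dtype=float)
        bp = np.interp(c, self.cumulative_cm, self.positions_bp)
        return float(bp) if np.isscalar(cm) else bp

    @property
    def total_morgans(self) -> float:
        return float(self.cumulative_cm[-1] - self.cumulative_cm[0]) / 100.0

    def morgans_between(self, pos_a: float, pos_b: float) -> float:
        return abs(self.cm_at(pos_b) - self.cm_at(pos_a)) / 100.0

    # -- TSV I/O (chrom, pos, rate cM/Mb, cumulative cM) -------------------

    def to_tsv(self, path: str) -> None:
        df = pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.positions_bp.astype(np.int64),
                "rate_cm_mb": self.rates_cm_per_mb,
                "cm": self.cumulative_cm,
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "GeneticMap":
        df = pd.read_csv(path, sep="\t")
        chrom = str(df.iloc[0, 0])
        return cls(
            chrom,
            df.iloc[:, 1].to_numpy(float),
            df.iloc[:, 3].to_numpy(float),
            df.iloc[:, 2].to_numpy(float),
        )


def read_phenotypes(path: str) -> pd.DataFrame:
    """Read a phenotype table (TSV with a header; first column sample IDs)."""
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={df.columns[0]: "sample_id"})
    return df


def write_phenotypes(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)
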