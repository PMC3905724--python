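"""Forward simulation of a population isolate with known ground truth.

The simulator emulates the statistical structure of a small founder
population: a bottleneck of ``n_founders`` individuals, discrete
non-overlapping generations of random mating, recombination as a Poisson
process at one crossover per Morgan on the genetic-map scale (Haldane, no
interference), a single founder haplotype carrying a rare derived allele
that drifts to a configurable final frequency, and genotyping error and
missingness injected into the released genotype matrix.  Haplotypes are
represented internally as ancestry mosaics over founder haplotypes, which
makes true identity-by-descent segments around the focal allele exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, GeneticMap


@dataclass
class IsolateConfig:
    """Configuration of one simulated isolate cohort.

    ``pop_size_trajectory`` gives the size of each post-founder generation;
    by default it grows geometrically from the founder count to ten times
    the founder count.  ``carrier_target_freq`` is the desired final derived-
    allele frequency; whole replicates are rejection-resampled (bounded by
    ``max_attempts``) until the realised frequency falls within
    ``freq_tol``.  Set it to ``None`` for a single unconditioned run.
    """

    n_founders: int = 40
    n_generations: int = 10
    pop_size_trajectory: list[int] | None = None
    chrom_length_bp: int = 10_000_000
    n_variants: int = 400
    map_model: dict | GeneticMap | None = None  # default: uniform 1 cM/Mb
    carrier_target_freq: float | None = 0.019
    freq_tol: float = 0.01
    genotype_error_rate: float = 0.01
    missing_rate: float = 0.0
    founder_maf_range: tuple[float, float] = (0.1, 0.5)
    seed: int = 0
    max_attempts: int = 500

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise ValueError("need at least two founders")
        if self.chrom_length_bp <= 0:
            raise ValueError("chromosome length must be positive")
        for name in ("genotype_error_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.carrier_target_freq is not None and not 0 < self.carrier_target_freq < 1:
            raise ValueError("carrier_target_freq must lie in (0, 1)")
        if self.pop_size_trajectory is None:
            ratio = 10.0 ** (1.0 / max(self.n_generations, 1))
            sizes = [
                max(2, int(round(self.n_founders * ratio**g)))
                for g in range(1, self.n_generations + 1)
            ]
            self.pop_size_trajectory = sizes
        if len(self.pop_size_trajectory) != self.n_generations:
            raise ValueError("trajectory length must equal n_generations")
        if any(s < 2 for s in self.pop_size_trajectory):
            raise ValueError("population sizes must be at least 2")

    def build_map(self) -> GeneticMap:
        m = self.map_model
        if isinstance(m, GeneticMap):
            return m
        if m is None:
            return GeneticMap.uniform("1", self.chrom_length_bp, 1.0)
        if m.get("type", "uniform") == "uniform":
            return GeneticMap.uniform("1", self.chrom_length_bp, m.get("cm_per_mb", 1.0))
        if m["type"] == "piecewise":
            return GeneticMap.piecewise("1", m["breakpoints_bp"], m["rates_cm_mb"])
        raise ValueError(f"unknown map model {m!r}")


@dataclass
class TraitConfig:
    """Additive quantitative-trait model on top of the simulated genotypes.

    The focal variant contributes ``variance_explained_target`` of the trait
    variance (or a fixed per-allele ``variant_beta`` if given), a polygenic
    component with covariance proportional to the kinship matrix contributes
    ``polygenic_h2``, and the remainder is independent noise.  ``mean`` and
    ``sd`` set the trait scale.
    """

    trait_name: str = "HDL"
    variant_beta: float | None = None
    variance_explained_target: float = 0.029
    polygenic_h2: float = 0.3
    mean: float = 1.265
    sd: float = 0.35

    def __post_init__(self) -> None:
        if not 0 <= self.variance_explained_target <= 1:
            raise ValueError("variance_explained_target must lie in [0, 1]")
        if not 0 <= self.polygenic_h2 <= 1:
            raise ValueError("polygenic_h2 must lie in [0, 1]")
        if self.variance_explained_target + self.polygenic_h2 > 1:
            raise ValueError("variance fractions must sum to at most 1")
        if self.sd <= 0:
            raise ValueError("sd must be positive")


@dataclass
class SimTruth:
    """Ground truth of one simulated cohort (final generation)."""

    sample_ids: list[str]
    haplotypes: np.ndarray  # (n, 2, m) error-free alleles
    founder_haplotypes: np.ndarray  # (2*n_founders, m)
    pedigree: pd.DataFrame  # generation, individual, parent1, parent2
    carrier_status: np.ndarray  # derived-allele copies per individual
    ibd_segments: pd.DataFrame  # true pairwise IBD around the focal variant
    focal_index: int
    focal_pos: int
    trait_params: dict | None = None
    ancestry: list = field(default_factory=list, repr=False)  # per-individual mosaics


# ---------------------------------------------------------------------------
# recombination machinery (ancestry mosaics on the cM scale)
# ---------------------------------------------------------------------------
# A mosaic is a pair (starts, ids): piecewise-constant founder-haplotype ids
# along [0, L_cm); segment k covers [starts[k], starts[k+1]).


def draw_recombination_breakpoints(rng: np.random.Generator, gmap: GeneticMap) -> np.ndarray:
    """Crossover positions (in cumulative cM) for one meiosis: a Poisson
    process at rate 1 per Morgan along the map."""
    total_m = gmap.total_morgans
    k = rng.poisson(total_m)
    if k == 0:
        return np.empty(0)
    lo, hi = gmap.cumulative_cm[0], gmap.cumulative_cm[-1]
    return np.sort(rng.uniform(lo, hi, size=k))


def _slice_mosaic(starts, ids, a: float, b: float):
    i0 = int(np.searchsorted(starts, a, side="right")) - 1
    i1 = int(np.searchsorted(starts, b, side="left"))
    seg_starts = np.concatenate([[a], starts[i0 + 1 : i1]])
    seg_ids = ids[i0:i1]
    return seg_starts, seg_ids


def _recombine(mosaic0, mosaic1, breaks: np.ndarray, phase: int, lo: float, hi: float):
    """Gamete mosaic: splice of the two parental mosaics, switching source at
    each breakpoint, starting from ``phase``."""
    bounds = np.concatenate([[lo], breaks, [hi]])
    out_starts: list[float] = []
    out_ids: list[int] = []
    src = (mosaic0, mosaic1)
    cur = phase
    for k in range(len(bounds) - 1):
        a, b = bounds[k], bounds[k + 1]
        if a >= b:
            cur ^= 1
            continue
        starts, ids = _slice_mosaic(src[cur][0], src[cur][1], a, b)
        for s, i in zip(starts, ids):
            if out_ids and out_ids[-1] == i:
                continue  # merge adjacent identical ancestry
            out_starts.append(float(s))
            out_ids.append(int(i))
        cur ^= 1
    return np.array(out_starts), np.array(out_ids, dtype=np.int32)


def _ancestry_at(mosaic, cm) -> np.ndarray:
    starts, ids = mosaic
    j = np.searchsorted(starts, np.asarray(cm, dtype=float), side="right") - 1
    return ids[np.clip(j, 0, len(ids) - 1)]


def _run_pedigree(cfg: IsolateConfig, gmap: GeneticMap, rng: np.random.Generator):
    """Simulate the mosaic genealogy; returns final-gen mosaics + pedigree."""
    lo = float(gmap.cumulative_cm[0])
    hi = float(gmap.cumulative_cm[-1])
    pop = [
        [
            (np.array([lo]), np.array([2 * i], dtype=np.int32)),
            (np.array([lo]), np.array([2 * i + 1], dtype=np.int32)),
        ]
        for i in range(cfg.n_founders)
    ]
    ped_rows = [(0, i, -1, -1) for i in range(cfg.n_founders)]
    for gen, size in enumerate(cfg.pop_size_trajectory, start=1):
        new_pop = []
        n_par = len(pop)
        for child in range(size):
            p1 = int(rng.integers(n_par))
            p2 = int(rng.integers(n_par - 1))
            if p2 >= p1:
                p2 += 1  # selfing disallowed
            gametes = []
            for p in (p1, p2):
                breaks = draw_recombination_breakpoints(rng, gmap)
                phase = int(rng.integers(2))
                gametes.append(_recombine(pop[p][0], pop[p][1], breaks, phase, lo, hi))
            new_pop.append(gametes)
            ped_rows.append((gen, child, p1, p2))
        pop = new_pop
    pedigree = pd.DataFrame(ped_rows, columns=["generation", "individual", "parent1", "parent2"])
    return pop, pedigree


def _true_ibd_segments(
    mosaics, carrier_haps, focal_cm: float, gmap: GeneticMap, sample_ids
) -> pd.DataFrame:
    """Pairwise true IBD intervals: intersection of the founder-hap-0 runs
    containing the focal position, for every pair of carrier haplotypes."""
    runs = {}
    for (i, h) in carrier_haps:
        starts, ids = mosaics[i][h]
        k = int(np.searchsorted(starts, focal_cm, side="right")) - 1
        a = starts[k]
        b = starts[k + 1] if k + 1 < len(starts) else gmap.cumulative_cm[-1]
        runs[(i, h)] = (a, b)
    rows = []
    keys = sorted(runs)
    for x in range(len(keys)):
        for y in range(x + 1, len(keys)):
            (i, hi_), (j, hj) = keys[x], keys[y]
            a = max(runs[keys[x]][0], runs[keys[y]][0])
            b = min(runs[keys[x]][1], runs[keys[y]][1])
            rows.append(
                {
                    "sample_i": sample_ids[i],
                    "hap_i": hi_,
                    "sample_j": sample_ids[j],
                    "hap_j": hj,
                    "start_bp": int(round(gmap.bp_at(a))),
                    "end_bp": int(round(gmap.bp_at(b))),
                    "start_cm": float(a),
                    "end_cm": float(b),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "sample_i", "hap_i", "sample_j", "hap_j",
            "start_bp", "end_bp", "start_cm", "end_cm",
        ],
    )
    return df.sort_values("start_bp", kind="stable").reset_index(drop=True)


def simulate_isolate(cfg: IsolateConfig) -> tuple[GenotypeMatrix, SimTruth, GeneticMap]:
    """Simulate one isolate cohort.

    Exactly one founder haplotype (id 0) carries the derived focal allele.
    When ``carrier_target_freq`` is set, whole runs are resampled until the
    final-generation frequency lies within ``freq_tol`` of the target
    (conditioning on survival keeps the drift dynamics otherwise unbiased);
    a clear error is raised if the budget of ``max_attempts`` is exhausted.
    """
    rng = np.random.default_rng(cfg.seed)
    gmap = cfg.build_map()

    # variant positions: strictly increasing, spanning the chromosome
    pos = np.sort(
        rng.choice(
            np.arange(1, cfg.chrom_length_bp + 1), size=cfg.n_variants, replace=False
        )
    ).astype(np.int64)
    var_cm = np.asarray(gmap.cm_at(pos.astype(float)), dtype=float)
    focal_index = int(np.argmin(np.abs(pos - cfg.chrom_length_bp // 2)))
    focal_cm = float(var_cm[focal_index])
    focal_pos = int(pos[focal_index])

    mosaics = pedigree = None
    for attempt in range(cfg.max_attempts):
        mosaics_try, pedigree_try = _run_pedigree(cfg, gmap, rng)
        anc = np.array(
            [_ancestry_at(h, [focal_cm])[0] for ind in mosaics_try for h in ind]
        )
        freq = float((anc == 0).mean())
        if cfg.carrier_target_freq is None or abs(freq - cfg.carrier_target_freq) <= cfg.freq_tol:
            mosaics, pedigree = mosaics_try, pedigree_try
            break
    if mosaics is None:
        raise RuntimeError(
            f"target frequency {cfg.carrier_target_freq} not reached within "
            f"{cfg.max_attempts} attempts (tolerance {cfg.freq_tol}); "
            "widen freq_tol, raise max_attempts, or change the demography"
        )

    # founder alleles: background markers at moderate frequency, one focal
    # derived allele private to founder haplotype 0
    n_hap = 2 * cfg.n_founders
    lo_f, hi_f = cfg.founder_maf_range
    maf = rng.uniform(lo_f, hi_f, size=cfg.n_variants)
    founder = (rng.random((n_hap, cfg.n_variants)) < maf).astype(np.uint8)
    founder[:, focal_index] = 0
    founder[0, focal_index] = 1

    n = len(mosaics)
    sample_ids = [f"S{i:04d}" for i in range(n)]
    haplotypes = np.empty((n, 2, cfg.n_variants), dtype=np.uint8)
    carrier_haps = []
    for i, ind in enumerate(mosaics):
        for h in (0, 1):
            anc_ids = _ancestry_at(ind[h], var_cm)
            haplotypes[i, h] = founder[anc_ids, np.arange(cfg.n_variants)]
            if anc_ids[focal_index] == 0:
                carrier_haps.append((i, h))
    carrier_status = haplotypes[:, :, focal_index].sum(axis=1).astype(np.int8)

    genotypes = haplotypes.sum(axis=1).astype(np.int8)
    if cfg.genotype_error_rate > 0:
        err = rng.random(genotypes.shape) < cfg.genotype_error_rate
        if err.any():
            wrong = rng.integers(1, 3, size=int(err.sum()))
            genotypes[err] = (genotypes[err] + wrong) % 3  # uniform over the 2 others
    if cfg.missing_rate > 0:
        miss = rng.random(genotypes.shape) < cfg.missing_rate
        genotypes[miss] = MISSING

    variants = pd.DataFrame(
        {
            "chrom": gmap.chrom,
            "pos": pos,
            "id": [f"var{j:05d}" for j in range(cfg.n_variants)],
            "ref": "C",
            "alt": "T",
        }
    )
    g = GenotypeMatrix(genotypes, sample_ids, variants)
    ibd = _true_ibd_segments(mosaics, carrier_haps, focal_cm, gmap, sample_ids)
    truth = SimTruth(
        sample_ids=sample_ids,
        haplotypes=haplotypes,
        founder_haplotypes=founder,
        pedigree=pedigree,
        carrier_status=carrier_status,
        ibd_segments=ibd,
        focal_index=focal_index,
        focal_pos=focal_pos,
        ancestry=mosaics,
    )
    return g, truth, gmap


def simulate_traits(
    truth: SimTruth, config: TraitConfig, kinship, seed: int = 0
) -> pd.DataFrame:
    """Simulate a quantitative trait on the cohort.

    trait = mean + beta * copies + polygenic(K) + residual, with the
    polygenic component drawn with covariance proportional to the kinship
    matrix (normalised to unit mean diagonal).  A non-positive-semidefinite
    kinship matrix is rejected.
    """
    rng = np.random.default_rng(seed)
    n = len(truth.sample_ids)
    K = np.asarray(kinship.values if hasattr(kinship, "values") else kinship, dtype=float)
    if K.shape != (n, n):
        raise ValueError("kinship dimensions do not match sample count")
    diagonal = np.count_nonzero(K - np.diag(np.diag(K))) == 0
    if diagonal:
        w, V = np.diag(K).copy(), None
    else:
        w, V = np.linalg.eigh((K + K.T) / 2.0)
    if w.min() < -1e-8 * max(1.0, abs(w.max())):
        raise ValueError("kinship matrix is not positive semi-definite")
    w = np.clip(w, 0.0, None)

    copies = truth.carrier_status.astype(float)
    f = copies.mean() / 2.0
    ve = config.variance_explained_target
    if config.variant_beta is not None:
        beta = config.variant_beta
    else:
        if ve > 0 and not 0 < f < 1:
            raise ValueError("focal variant is monomorphic; cannot target VE")
        beta_std = np.sqrt(ve / (2 * f * (1 - f))) if ve > 0 else 0.0
        beta = beta_std * config.sd

    diag_mean = K.diagonal().mean() if K.diagonal().mean() > 0 else 1.0
    if config.polygenic_h2 > 0:
        z = np.sqrt(w) * rng.standard_normal(n)
        if V is not None:
            z = V @ z
        polygenic = z / np.sqrt(diag_mean) * np.sqrt(config.polygenic_h2) * config.sd
    else:
        polygenic = np.zeros(n)
    resid_sd = config.sd * np.sqrt(max(1.0 - ve - config.polygenic_h2, 0.0))
    y = config.mean + beta * copies + polygenic + rng.standard_normal(n) * resid_sd

    truth.trait_params = {
        "trait_name": config.trait_name,
        "variant_beta": float(beta),
        "variance_explained_target": float(ve),
        "polygenic_h2": float(config.polygenic_h2),
        "mean": float(config.mean),
        "sd": float(config.sd),
        "realized_freq": float(f),
    }
    return pd.DataFrame({"sample_id": truth.sample_ids, config.trait_name: y})


# ---------------------------------------------------------------------------
# truth round-trip
# ---------------------------------------------------------------------------


def write_truth(truth: SimTruth, out_dir: str) -> None:
    """Write the ground truth as plain TSV files (lossless round trip)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"sample_id": truth.sample_ids, "copies": truth.carrier_status}
    ).to_csv(out / "carriers.tsv", sep="\t", index=False)
    truth.pedigree.to_csv(out / "pedigree.tsv", sep="\t", index=False)
    truth.ibd_segments.sort_values("start_bp", kind="stable").to_csv(
        out / "ibd_segments.tsv", sep="\t", index=False
    )
    n, _, m = truth.haplotypes.shape
    hap_df = pd.DataFrame(
        truth.haplotypes.reshape(2 * n, m),
        index=pd.MultiIndex.from_product([truth.sample_ids, [0, 1]]),
    )
    hap_df.index.names = ["sample_id", "hap"]
    hap_df.reset_index().to_csv(out / "haplotypes.tsv", sep="\t", index=False)
    pd.DataFrame(truth.founder_haplotypes).to_csv(
        out / "founder_haplotypes.tsv", sep="\t", index=False
    )
    meta = {"focal_index": truth.focal_index, "focal_pos": truth.focal_pos}
    if truth.trait_params:
        meta.update(truth.trait_params)
    pd.Series(meta).to_csv(out / "meta.tsv", sep="\t", header=False)


def read_truth(in_dir: str) -> SimTruth:
    """Read ground truth written by :func:`write_truth`."""
    p = Path(in_dir)
    carriers = pd.read_csv(p / "carriers.tsv", sep="\t")
    pedigree = pd.read_csv(p / "pedigree.tsv", sep="\t")
    ibd = pd.read_csv(p / "ibd_segments.tsv", sep="\t")
    hap_df = pd.read_csv(p / "haplotypes.tsv", sep="\t")
    sample_ids = carriers["sample_id"].tolist()
    m = hap_df.shape[1] - 2
    haplotypes = (
        hap_df.drop(columns=["sample_id", "hap"])
        .to_numpy(np.uint8)
        .reshape(len(sample_ids), 2, m)
    )
    founder = pd.read_csv(p / "founder_haplotypes.tsv", sep="\t").to_numpy(np.uint8)
    meta = pd.read_csv(p / "meta.tsv", sep="\t", header=None, index_col=0)[1]
    trait_keys = set(meta.index) - {"focal_index", "focal_pos"}
    trait_params = None
    if trait_keys:
        trait_params = {}
        for k in trait_keys:
            v = meta[k]
            try:
                trait_params[k] = float(v)
            except (TypeError, ValueError):
                trait_params[k] = v
    return SimTruth(
        sample_ids=sample_ids,
        haplotypes=haplotypes,
        founder_haplotypes=founder,
        pedigree=pedigree,
        carrier_status=carriers["copies"].to_numpy(np.int8),
        ibd_segments=ibd,
        focal_index=int(meta["focal_index"]),
        focal_pos=int(meta["focal_pos"]),
        trait_params=trait_params,
    )
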