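"""Maximal haplotype identity via a surrogate-parent Viterbi HMM.

For a target individual, every other cohort member is a candidate "surrogate
parent".  The hidden state of the HMM is the pair of surrogates (a left and a
right slot, one per target chromosome); the emission probability at each
variant is the chance that the target's observed genotype arises from each
surrogate transmitting one allele drawn uniformly from its own genotype,
allowing a small genotype-error probability.  Between adjacent variants at
genetic distance d Morgans each surrogate independently switches with
probability 1 - exp(-switch_rate * d), redrawing uniformly from the
candidate set.  The Viterbi path through this chain identifies, at every
position, the genealogical nearest neighbours of the target's two
chromosomes; the maximal run over which the focal-side surrogate is
unchanged is the shared-haplotype segment.

All HMM arithmetic is carried out in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MISSING, GenotypeMatrix, GeneticMap


@dataclass
class LRPConfig:
    """Long-range-phasing style surrogate-parent HMM settings.

    error_rate: per-genotype miscall probability (uniform over the two wrong
    genotype values).  switch_rate: surrogate-change intensity per Morgan.
    relatedness_cap: candidates must have kinship below this value to the
    target (when a kinship matrix is supplied).
    """

    error_rate: float = 0.01
    switch_rate: float = 1.0
    candidate_set: list[str] | None = None
    relatedness_cap: float = 0.2

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must lie in [0, 0.5)")
        if self.switch_rate <= 0:
            raise ValueError("switch_rate must be positive")


@dataclass
class SharedSegment:
    """A maximal haplotype-identity interval around a focal position.

    Coordinates are 1-based and closed, at the outermost compatible variant
    positions (never extended into untyped gaps).
    """

    target: str
    surrogate: str | None
    side: str  # "left" | "right" | "pair"
    chrom: str
    start_bp: int
    end_bp: int
    start_cm: float
    end_cm: float
    focal_pos: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def length_cm(self) -> float:
        return self.end_cm - self.start_cm

    @property
    def contains_focal(self) -> bool:
        return self.start_bp <= self.focal_pos <= self.end_bp


@dataclass
class ViterbiPath:
    """Decoded surrogate-parent path for one target."""

    target: str
    candidates: list[str]
    path: np.ndarray  # (n_variants, 2) indices into candidates
    log_prob: float
    positions_bp: np.ndarray
    positions_cm: np.ndarray
    chrom: str


@dataclass
class SharingProfile:
    """Per-target maximal-identity lengths on a grid of positions."""

    grid_bp: np.ndarray
    grid_cm: np.ndarray
    targets: list[str]
    lengths_bp: np.ndarray  # (n_targets, n_grid)
    lengths_cm: np.ndarray
    carrier: np.ndarray  # bool per target
    chrom: str = "1"


def _candidate_indices(
    g: GenotypeMatrix, target: str, cfg: LRPConfig, kinship=None
) -> list[int]:
    ti = g.sample_index(target)
    if cfg.candidate_set is not None:
        idx = [g.sample_index(s) for s in cfg.candidate_set if s != target]
    elif kinship is not None:
        row = kinship.values[ti]
        idx = [
            i for i in range(g.n_samples) if i != ti and row[i] < cfg.relatedness_cap
        ]
    else:
        idx = [i for i in range(g.n_samples) if i != ti]
    if len(idx) < 2:
        raise ValueError("need at least two surrogate-parent candidates")
    return idx


def _emission_logprob(
    target_geno: np.ndarray, cand_geno: np.ndarray, error_rate: float
) -> "callable":
    """Return ``emit(j) -> (N, N) log emission matrix`` for variant j.

    Transmission probability of the alt allele from candidate c with genotype
    g is g/2; a missing candidate genotype transmits either allele with
    probability 1/2.  A missing target genotype is uninformative (log 1).
    """
    p = cand_geno.astype(float) / 2.0
    p[cand_geno == MISSING] = 0.5
    e = error_rate

    def emit(j: int) -> np.ndarray:
        n = p.shape[0]
        obs = target_geno[j]
        if obs == MISSING:
            return np.zeros((n, n))
        pi = p[:, j][:, None]
        pj = p[:, j][None, :]
        t0 = (1 - pi) * (1 - pj)
        t1 = pi * (1 - pj) + (1 - pi) * pj
        t2 = pi * pj
        probs = [t0, t1, t2]
        lik = sum(
            probs[t] * ((1 - e) if t == obs else e / 2.0) for t in range(3)
        )
        with np.errstate(divide="ignore"):
            return np.log(lik)

    return emit


def viterbi_surrogate_parents(
    g: GenotypeMatrix,
    target: str,
    gmap: GeneticMap,
    cfg: LRPConfig | None = None,
    kinship=None,
) -> ViterbiPath:
    """Decode the maximum-probability surrogate-parent-pair path.

    Ties are broken deterministically towards the lowest candidate index and
    towards keeping the current surrogates.
    """
    cfg = cfg or LRPConfig()
    idx = _candidate_indices(g, target, cfg, kinship)
    ti = g.sample_index(target)
    pos = g.positions.astype(float)
    lo, hi = gmap.positions_bp[0], gmap.positions_bp[-1]
    if pos.min() < lo or pos.max() > hi:
        raise ValueError("genetic map does not cover all variant positions")
    cm = np.asarray(gmap.cm_at(pos), dtype=float)

    tgt = g.genotypes[ti, :]
    cand = g.genotypes[idx, :]
    n = len(idx)
    m = g.n_variants
    emit = _emission_logprob(tgt, cand, cfg.error_rate)

    v = np.full((n, n), -np.log(n * n)) + emit(0)
    choices = np.empty((m - 1, n, n), dtype=np.uint8)
    row_args = np.empty((m - 1, n), dtype=np.int32)
    col_args = np.empty((m - 1, n), dtype=np.int32)
    glob_args = np.empty((m - 1, 2), dtype=np.int32)

    d_morgans = np.diff(cm) / 100.0
    for t in range(1, m):
        s = 1.0 - np.exp(-cfg.switch_rate * d_morgans[t - 1])
        with np.errstate(divide="ignore"):
            stay = np.log((1.0 - s) + s / n)
            switch = np.log(s / n) if s > 0 else -np.inf

        row_max = v.max(axis=1)
        row_arg = v.argmax(axis=1)
        col_max = v.max(axis=0)
        col_arg = v.argmax(axis=0)
        gflat = int(v.argmax())
        gi, gj = divmod(gflat, n)
        gmax = v[gi, gj]

        term1 = v + 2.0 * stay  # both surrogates kept
        term2 = row_max[:, None] + stay + switch  # right switched
        term3 = col_max[None, :] + switch + stay  # left switched
        term4 = gmax + 2.0 * switch  # both switched

        best = term1
        choice = np.zeros((n, n), dtype=np.uint8)
        for code, term in ((1, term2), (2, term3), (3, np.full((n, n), term4))):
            upd = term > best
            best = np.where(upd, term, best)
            choice[upd] = code

        v = best + emit(t)
        choices[t - 1] = choice
        row_args[t - 1] = row_arg
        col_args[t - 1] = col_arg
        glob_args[t - 1] = (gi, gj)

    flat = int(v.argmax())
    ci, cj = divmod(flat, n)
    log_prob = float(v[ci, cj])

    path = np.empty((m, 2), dtype=np.int32)
    path[m - 1] = (ci, cj)
    for t in range(m - 1, 0, -1):
        c = choices[t - 1, ci, cj]
        if c == 0:
            pass
        elif c == 1:
            cj = int(row_args[t - 1, ci])
        elif c == 2:
            ci = int(col_args[t - 1, cj])
        else:
            ci, cj = (int(glob_args[t - 1, 0]), int(glob_args[t - 1, 1]))
        path[t - 1] = (ci, cj)

    return ViterbiPath(
        target=target,
        candidates=[g.samples[i] for i in idx],
        path=path,
        log_prob=log_prob,
        positions_bp=pos.astype(np.int64),
        positions_cm=cm,
        chrom=str(g.variants["chrom"].iloc[0]),
    )


def _focal_index(positions: np.ndarray, focal_pos: float) -> int:
    if focal_pos < positions[0] or focal_pos > positions[-1]:
        raise ValueError("focal position outside the typed variant range")
    j = int(np.searchsorted(positions, focal_pos))
    if j == len(positions) or (
        j > 0 and abs(positions[j - 1] - focal_pos) <= abs(positions[j] - focal_pos)
    ):
        j -= 1
    return j


def segments_at(vp: ViterbiPath, focal_pos: int) -> tuple[SharedSegment, SharedSegment]:
    """Left- and right-slot shared segments around a focal position: the
    maximal run of variants over which the slot's surrogate is unchanged."""
    fi = _focal_index(vp.positions_bp, focal_pos)
    out = []
    for slot, side in ((0, "left"), (1, "right")):
        states = vp.path[:, slot]
        a = fi
        while a > 0 and states[a - 1] == states[fi]:
            a -= 1
        b = fi
        while b < len(states) - 1 and states[b + 1] == states[fi]:
            b += 1
        out.append(
            SharedSegment(
                target=vp.target,
                surrogate=vp.candidates[int(states[fi])],
                side=side,
                chrom=vp.chrom,
                start_bp=int(vp.positions_bp[a]),
                end_bp=int(vp.positions_bp[b]),
                start_cm=float(vp.positions_cm[a]),
                end_cm=float(vp.positions_cm[b]),
                focal_pos=int(focal_pos),
            )
        )
    return out[0], out[1]


def maximal_identity_pair(
    g: GenotypeMatrix,
    sample_a: str,
    sample_b: str,
    focal_pos: int,
    gmap: GeneticMap,
    max_mismatch: int = 0,
) -> SharedSegment:
    """Direct-scan maximal haplotype identity between two samples.

    The maximal closed interval containing the focal position in which the
    pair shows at most ``max_mismatch`` opposite-homozygote genotypes (the
    only configuration incompatible with sharing one haplotype).  Serves as
    the brute-force cross-check for the HMM decoding.
    """
    ia, ib = g.sample_index(sample_a), g.sample_index(sample_b)
    pos = g.positions
    fi = _focal_index(pos, focal_pos)
    ga, gb = g.genotypes[ia], g.genotypes[ib]
    viol = np.flatnonzero(
        ((ga == 0) & (gb == 2)) | ((ga == 2) & (gb == 0))
    )
    m = len(pos)
    k = max_mismatch

    idx = int(np.searchsorted(viol, fi, side="left"))
    best = None  # (length_bp, lo, hi)
    for i in range(max(0, idx - k), idx + 1):
        j = min(len(viol), i + k)
        lo = int(viol[i - 1]) + 1 if i > 0 else 0
        hi = int(viol[j]) - 1 if j < len(viol) else m - 1
        if lo > hi or not (lo <= fi <= hi):
            continue
        length = int(pos[hi] - pos[lo])
        if best is None or length > best[0]:
            best = (length, lo, hi)
    if best is None:  # focal variant itself is a violation
        best = (0, fi, fi)
    _, lo, hi = best
    cm = gmap.cm_at(pos[[lo, hi]].astype(float))
    return SharedSegment(
        target=sample_a,
        surrogate=sample_b,
        side="pair",
        chrom=str(g.variants["chrom"].iloc[0]),
        start_bp=int(pos[lo]),
        end_bp=int(pos[hi]),
        start_cm=float(cm[0]),
        end_cm=float(cm[1]),
        focal_pos=int(focal_pos),
    )


def sharing_profile(
    g: GenotypeMatrix,
    gmap: GeneticMap,
    cfg: LRPConfig | None = None,
    grid: np.ndarray | None = None,
    targets: list[str] | None = None,
    carriers: set[str] | None = None,
    kinship=None,
) -> SharingProfile:
    """Maximal-identity length of each target's nearest genealogical
    neighbour at each grid position.

    One Viterbi decoding per target; at every grid point the longer of the
    two slot segments (in cM) is recorded.
    """
    cfg = cfg or LRPConfig()
    if grid is None or len(grid) == 0:
        raise ValueError("grid must be non-empty")
    grid = np.asarray(grid, dtype=float)
    targets = targets if targets is not None else list(g.samples)
    carriers = carriers or set()

    lengths_bp = np.zeros((len(targets), len(grid)))
    lengths_cm = np.zeros((len(targets), len(grid)))
    for i, t in enumerate(targets):
        vp = viterbi_surrogate_parents(g, t, gmap, cfg, kinship=kinship)
        for j, pos in enumerate(grid):
            left, right = segments_at(vp, int(pos))
            seg = left if left.length_cm >= right.length_cm else right
            lengths_bp[i, j] = seg.length_bp
            lengths_cm[i, j] = seg.length_cm
    return SharingProfile(
        grid_bp=grid.astype(np.int64),
        grid_cm=np.asarray(gmap.cm_at(grid), dtype=float),
        targets=list(targets),
        lengths_bp=lengths_bp,
        lengths_cm=lengths_cm,
        carrier=np.array([t in carriers for t in targets]),
        chrom=str(g.variants["chrom"].iloc[0]),
    )


def compare_carriers(profile: SharingProfile, focal_pos: int):
    """Two-sample Kolmogorov-Smirnov test of carrier vs non-carrier
    maximal-identity lengths at the grid point nearest the focal position."""
    j = int(np.argmin(np.abs(profile.grid_bp - focal_pos)))
    x = profile.lengths_cm[profile.carrier, j]
    y = profile.lengths_cm[~profile.carrier, j]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least two carriers and two non-carriers")
    res = stats.ks_2samp(x, y)
    return float(res.statistic), float(res.pvalue)


def estimate_generations(lengths_cm, conf: float = 0.95) -> dict[str, float]:
    """Generations to the common ancestor from shared-segment lengths.

    Model: the segment extends beyond the focal point to the left and right
    by independent exponential distances with rate 2G per Morgan (the 2G
    meioses separating the pair through an ancestor G generations back), so
    the total length is Gamma(shape 2, rate 2G).  The MLE is
    G-hat = 1 / mean(length in Morgans); the confidence interval follows from
    the Gamma sampling distribution of the mean.
    """
    lengths = np.asarray(list(lengths_cm), dtype=float)
    if len(lengths) == 0 or np.any(lengths <= 0):
        raise ValueError("lengths must be positive")
    morgans = lengths / 100.0
    n = len(morgans)
    mean = morgans.mean()
    g_hat = 1.0 / mean
    alpha = 1.0 - conf
    # 2 G n mean ~ Gamma(2n, 1)
    lo = stats.gamma.ppf(alpha / 2.0, 2 * n) / (2 * n * mean)
    hi = stats.gamma.ppf(1.0 - alpha / 2.0, 2 * n) / (2 * n * mean)
    return {"g_hat": float(g_hat), "ci_low": float(lo), "ci_high": float(hi), "n": n}


def generations_to_years(generations: float, generation_years: float = 25.0) -> float:
    """Age corresponding to a number of generations."""
    return float(generations * generation_years)


def excess_relatedness_decay(
    profile: SharingProfile, focal_pos: int, n_bins: int = 8
):
    """Excess carrier sharing by genetic distance from the focal position.

    Per grid point: mean carrier length minus mean non-carrier (background)
    length; binned by |cM - focal cM|.  An exponential decay rate is fitted
    by least squares on the log of the positive excess values; if no bin has
    positive excess the rate is undefined (None).

    Returns ``(table, rate_per_cm)``.
    """
    if profile.carrier.sum() < 2:
        raise ValueError("need at least two carriers")
    focal_cm = float(profile.grid_cm[np.argmin(np.abs(profile.grid_bp - focal_pos))])
    dist = np.abs(profile.grid_cm - focal_cm)
    excess = (
        profile.lengths_cm[profile.carrier].mean(axis=0)
        - profile.lengths_cm[~profile.carrier].mean(axis=0)
    )
    bins = np.linspace(0.0, dist.max() + 1e-9, n_bins + 1)
    which = np.clip(np.digitize(dist, bins) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        rows.append(
            {
                "dist_cm": float(dist[sel].mean()),
                "excess_cm": float(excess[sel].mean()),
                "n_points": int(sel.sum()),
            }
        )
    table = pd.DataFrame(rows)
    pos_rows = table[table["excess_cm"] > 0]
    if len(pos_rows) < 2:
        return table, None
    slope, _ = np.polyfit(pos_rows["dist_cm"], np.log(pos_rows["excess_cm"]), 1)
    return table, float(-slope)


def segments_to_bed(segments: list[SharedSegment], path: str) -> None:
    """Write segments as BED-like TSV (0-based half-open body converted from
    the internal 1-based closed coordinates, with cM columns appended)."""
    rows = [
        {
            "chrom": s.chrom,
            "start": s.start_bp - 1,
            "end": s.end_bp,
            "target": s.target,
            "surrogate": s.surrogate,
            "side": s.side,
            "start_cm": s.start_cm,
            "end_cm": s.end_cm,
            "focal_pos": s.focal_pos,
        }
        for s in segments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
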