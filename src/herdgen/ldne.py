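"""Linkage-disequilibrium decay and effective population size (Ne).

r² between two markers is the squared Pearson correlation of unphased
allele dosages over pairwise-complete individuals (composite LD).  Pairs
are binned by physical distance; base pairs map to Morgans with a fixed
recombination rate (default 1 cM/Mb — no linkage map ships with array
data).  Each bin yields one Ne estimate through the Sved relation

    E[r²] = 1 / (1 + 4 N_e c)   ⇔   N_e = (1 / 4c) (1/r² − 1)

with the mean distance of a bin addressing ancestral size roughly
t = 1/(2c) generations ago.  With n genotyped individuals the expected
sampling inflation of r² is about 1/(2n); subtracting it before inverting
("sample-size correction") reduces the downward bias of Ne.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import MISSING, GenotypeDataset

#: floor applied to the corrected r² so the Sved inversion stays finite
R2_EPSILON = 1e-6
DEFAULT_CM_PER_MB = 1.0


@dataclass
class LDBin:
    """Mean r² of marker pairs whose distance lies in [min, max) bp."""

    min_dist_bp: int
    max_dist_bp: int
    n_pairs: int  # eligible pairs with defined r² assigned to the bin
    mean_r2: float
    mean_c_morgans: float
    n_sampled: int = 0  # pairs actually averaged (after downsampling)


@dataclass
class NeEstimate:
    bin: LDBin
    t_generations: float
    ne: float
    r2_adjusted: float
    flagged: bool = False  # True when the correction floored r² at epsilon


@dataclass
class NeConfig:
    bin_edges_bp: np.ndarray = field(
        default_factory=lambda: np.geomspace(50_000, 5_000_000, 11).astype(np.int64)
    )
    max_pairs_per_bin: int = 10_000
    cm_per_mb: float = DEFAULT_CM_PER_MB
    correct_sample_size: bool = True
    seed: int = 0


def genotype_r2(x_calls: np.ndarray, y_calls: np.ndarray) -> float:
    """Squared dosage correlation over pairwise-complete individuals.

    Returns NaN when fewer than two complete pairs remain or either marker
    is monomorphic in the complete subset (undefined LD).
    """
    x = np.asarray(x_calls, dtype=np.float64)
    y = np.asarray(y_calls, dtype=np.float64)
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return float("nan")
    x, y = x[ok], y[ok]
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    r = ((x - x.mean()) * (y - y.mean())).mean() / (sx * sy)
    return float(r * r)


def binned_r2(
    ds: GenotypeDataset,
    bin_edges_bp: np.ndarray | None = None,
    max_pairs_per_bin: int = 10_000,
    seed: int = 0,
    cm_per_mb: float = DEFAULT_CM_PER_MB,
) -> tuple[list[LDBin], int]:
    """Mean r² per distance bin over same-chromosome marker pairs.

    Bins are half-open ``[edge_k, edge_{k+1})``.  A bin holding more than
    ``max_pairs_per_bin`` eligible pairs is downsampled uniformly with the
    given seed before averaging.  Returns ``(bins, n_excluded)`` where
    ``n_excluded`` counts in-range pairs whose r² is undefined.
    """
    edges = (
        np.geomspace(50_000, 5_000_000, 11).astype(np.int64)
        if bin_edges_bp is None
        else np.asarray(bin_edges_bp, dtype=np.int64)
    )
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    chrom, pos = ds.chromosomes, ds.positions
    for c in np.unique(chrom):
        if np.any(np.diff(pos[chrom == c]) < 0):
            raise ValueError(f"markers on chromosome {c} are not position-sorted")

    n_bins = len(edges) - 1
    pair_i: list[list[int]] = [[] for _ in range(n_bins)]
    pair_j: list[list[int]] = [[] for _ in range(n_bins)]
    lo, hi = int(edges[0]), int(edges[-1])

    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        p = pos[idx]
        # for each anchor, the window of partners within [lo, hi) downstream
        starts = np.searchsorted(p, p + lo, side="left")
        stops = np.searchsorted(p, p + hi, side="left")
        for a in range(len(idx)):
            for b in range(max(starts[a], a + 1), stops[a]):
                d = p[b] - p[a]
                k = int(np.searchsorted(edges, d, side="right")) - 1
                if 0 <= k < n_bins:
                    pair_i[k].append(idx[a])
                    pair_j[k].append(idx[b])

    rng = np.random.default_rng(seed)
    bins: list[LDBin] = []
    n_excluded = 0
    calls = ds.calls
    for k in range(n_bins):
        ii = np.asarray(pair_i[k], dtype=np.int64)
        jj = np.asarray(pair_j[k], dtype=np.int64)
        if len(ii) > max_pairs_per_bin:
            sel = rng.choice(len(ii), size=max_pairs_per_bin, replace=False)
            sel.sort()
            ii_s, jj_s = ii[sel], jj[sel]
        else:
            ii_s, jj_s = ii, jj
        r2s, dists = [], []
        n_bad_sampled = 0
        for a, b in zip(ii_s, jj_s):
            r2 = genotype_r2(calls[:, a], calls[:, b])
            if np.isnan(r2):
                n_bad_sampled += 1
                continue
            r2s.append(r2)
            dists.append(pos[b] - pos[a])
        # extrapolate the undefined fraction of a downsampled bin
        if len(ii) > len(ii_s) and len(ii_s) > 0:
            n_bad = int(round(n_bad_sampled * len(ii) / len(ii_s)))
        else:
            n_bad = n_bad_sampled
        n_excluded += n_bad
        mean_r2 = float(np.mean(r2s)) if r2s else float("nan")
        mean_c = (
            float(np.mean(dists)) * cm_per_mb * 1e-8 if dists else float("nan")
        )
        bins.append(
            LDBin(
                min_dist_bp=int(edges[k]),
                max_dist_bp=int(edges[k + 1]),
                n_pairs=len(ii) - n_bad,
                mean_r2=mean_r2,
                mean_c_morgans=mean_c,
                n_sampled=len(r2s),
            )
        )
    return bins, n_excluded


def sved_ne(
    r2: float, c_morgans: float, n_individuals: int | None = None
) -> tuple[float, float, bool]:
    """Invert the Sved relation: Ne = (1/4c)(1/r² − 1).

    With ``n_individuals`` the sampling term 1/(2n) is subtracted from r²
    first, floored at :data:`R2_EPSILON`.  Returns ``(ne, r2_adjusted,
    floored)``; ``floored`` flags an estimate driven to the epsilon floor
    (r² indistinguishable from sampling noise — Ne effectively unbounded).
    """
    if not 0.0 < r2 <= 1.0:
        raise ValueError(f"r2 must lie in (0, 1], got {r2}")
    if c_morgans <= 0.0:
        raise ValueError(f"c_morgans must be positive, got {c_morgans}")
    floored = False
    if n_individuals is not None:
        if n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        r2_adj = r2 - 1.0 / (2.0 * n_individuals)
        if r2_adj < R2_EPSILON:
            r2_adj = R2_EPSILON
            floored = True
    else:
        r2_adj = r2
    ne = (1.0 / (4.0 * c_morgans)) * (1.0 / r2_adj - 1.0)
    return float(ne), float(r2_adj), floored


def ne_trajectory(
    ds: GenotypeDataset, config: NeConfig | None = None
) -> tuple[list[NeEstimate], NeEstimate]:
    """Per-bin Ne estimates plus the headline (most recent generations) one.

    The headline estimate comes from the usable bin with the smallest
    t = 1/(2c), i.e. the largest-distance bin, which reflects the most
    recent ancestral generations.
    """
    cfg = config or NeConfig()
    bins, _ = binned_r2(
        ds,
        bin_edges_bp=cfg.bin_edges_bp,
        max_pairs_per_bin=cfg.max_pairs_per_bin,
        seed=cfg.seed,
        cm_per_mb=cfg.cm_per_mb,
    )
    n_ind = ds.n_samples if cfg.correct_sample_size else None
    estimates: list[NeEstimate] = []
    for b in bins:
        if b.n_pairs == 0 or not np.isfinite(b.mean_r2) or b.mean_r2 <= 0:
            continue
        ne, r2_adj, floored = sved_ne(b.mean_r2, b.mean_c_morgans, n_ind)
        estimates.append(
            NeEstimate(
                bin=b,
                t_generations=1.0 / (2.0 * b.mean_c_morgans),
                ne=ne,
                r2_adjusted=r2_adj,
                flagged=floored,
            )
        )
    if not estimates:
        raise ValueError("no usable distance bin (all empty or undefined r²)")
    headline = min(estimates, key=lambda e: e.t_generations)
    return estimates, headline


def trajectory_tsv(estimates: list[NeEstimate]) -> str:
    header = (
        "min_dist_bp\tmax_dist_bp\tn_pairs\tmean_r2\tr2_adjusted"
        "\tmean_c_morgans\tt_generations\tne\tflagged\n"
    )
    rows = [
        f"{e.bin.min_dist_bp}\t{e.bin.max_dist_bp}\t{e.bin.n_pairs}"
        f"\t{e.bin.mean_r2:.6g}\t{e.r2_adjusted:.6g}\t{e.bin.mean_c_morgans:.6g}"
        f"\t{e.t_generations:.6g}\t{e.ne:.6g}\t{int(e.flagged)}"
        for e in estimates
    ]
    return header + "\n".join(rows) + "\n"
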