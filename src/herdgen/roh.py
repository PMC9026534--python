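"""Runs of homozygosity (ROH) and the genomic inbreeding coefficient F_ROH.

Detection follows the sliding-window scheme of PLINK's ``--homozyg``:

(a) a window of ``window_snps`` consecutive SNPs slides one SNP at a time
    along each sample × chromosome; a window is *good* when it contains at
    most ``max_het_in_roh`` heterozygous and ``max_missing_in_roh`` missing
    calls;
(b) a SNP is *eligible* when the fraction of good windows among all
    windows containing it is at least ``window_threshold``;
(c) maximal runs of eligible SNPs are split wherever adjacent SNPs lie
    more than ``max_gap_bp`` apart;
(d) a candidate run exceeding the segment-level het/missing caps is split
    left-to-right at the offending call (which is dropped), so no emitted
    segment ever violates the caps; runs are then trimmed so both ends are
    homozygous non-missing calls;
(e) a run is emitted iff it has at least ``min_snps_in_roh`` SNPs, spans at
    least ``min_length_bp``, and is dense enough
    (length / n_snps ≤ ``min_density_bp_per_snp``).

Segment length is ``end_bp − start_bp`` (PLINK's KB-column convention).
A chromosome with fewer SNPs than the window size degenerates to a single
whole-chromosome window.  Step (d)'s segment-level caps go beyond PLINK's
window-only enforcement; pass ``segment_level_caps=False`` for strict
window-level emulation.

F_ROH per individual is the summed ROH length divided by the autosomal
genome length; for the pig (Sscrofa 10.2) that length is ~2,450,713 kb.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset

#: autosomal genome length of the pig, Sscrofa 10.2 assembly (kb)
PIG_AUTOSOME_LENGTH_KB = 2_450_713.0


@dataclass(frozen=True)
class ROHParams:
    min_snps_in_roh: int = 30
    window_snps: int = 50
    min_density_bp_per_snp: int = 1_000_000  # 1 SNP per 1000 kb
    max_het_in_roh: int = 1
    max_missing_in_roh: int = 1
    window_threshold: float = 0.05
    min_length_bp: int = 1_000_000
    max_gap_bp: int = 1_000_000
    segment_level_caps: bool = True

    def __post_init__(self) -> None:
        for name in (
            "min_snps_in_roh",
            "window_snps",
            "min_density_bp_per_snp",
            "min_length_bp",
            "max_gap_bp",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_het_in_roh < 0 or self.max_missing_in_roh < 0:
            raise ValueError("het/missing caps must be >= 0")
        if not 0.0 < self.window_threshold <= 1.0:
            raise ValueError("window_threshold must lie in (0, 1]")


@dataclass(frozen=True)
class ROHSegment:
    sample_id: str
    chromosome: int
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def length_mb(self) -> float:
        return self.length_bp / 1e6


@dataclass
class InbreedingResult:
    f_roh_per_sample: dict[str, float]
    population_mean: float
    autosome_length_kb: float

    def to_tsv(self) -> str:
        lines = ["sample_id\tf_roh"]
        lines += [f"{k}\t{v:.6f}" for k, v in self.f_roh_per_sample.items()]
        lines.append(f"#population_mean\t{self.population_mean:.6f}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def _eligible_snps(
    het: np.ndarray, miss: np.ndarray, params: ROHParams
) -> np.ndarray:
    """Step (a)+(b): per-SNP eligibility from sliding-window hit fractions."""
    m = len(het)
    w = min(params.window_snps, m)  # short chromosome -> one whole window
    n_windows = m - w + 1
    # het/missing counts per window via cumulative sums
    ch = np.concatenate(([0], np.cumsum(het)))
    cm = np.concatenate(([0], np.cumsum(miss)))
    het_w = ch[w:] - ch[:-w]
    mis_w = cm[w:] - cm[:-w]
    good = (het_w <= params.max_het_in_roh) & (
        mis_w <= params.max_missing_in_roh
    )
    # windows containing SNP i: start in [max(0, i-w+1), min(i, n_windows-1)]
    cg = np.concatenate(([0], np.cumsum(good)))
    i = np.arange(m)
    first = np.maximum(0, i - w + 1)
    last = np.minimum(i, n_windows - 1)
    n_cover = last - first + 1
    n_good = cg[last + 1] - cg[first]
    return n_good / n_cover >= params.window_threshold


def _split_on_gaps(
    run: np.ndarray, pos: np.ndarray, max_gap: int
) -> list[np.ndarray]:
    """Step (c): split an index run where adjacent SNPs are > max_gap apart."""
    if len(run) == 0:
        return []
    gaps = np.diff(pos[run])
    breaks = np.flatnonzero(gaps > max_gap)
    return np.split(run, breaks + 1)


def _split_on_caps(
    run: np.ndarray, het: np.ndarray, miss: np.ndarray, params: ROHParams
) -> list[np.ndarray]:
    """Step (d) part 1: greedy left-to-right split at cap-busting calls."""
    pieces: list[list[int]] = []
    cur: list[int] = []
    h = mi = 0
    for idx in run:
        if het[idx] and h + 1 > params.max_het_in_roh:
            if cur:
                pieces.append(cur)
            cur, h, mi = [], 0, 0
            continue  # the offending het is dropped
        if miss[idx] and mi + 1 > params.max_missing_in_roh:
            if cur:
                pieces.append(cur)
            cur, h, mi = [], 0, 0
            continue
        h += int(het[idx])
        mi += int(miss[idx])
        cur.append(int(idx))
    if cur:
        pieces.append(cur)
    return [np.asarray(p, dtype=np.int64) for p in pieces]


def _trim(run: np.ndarray, hom: np.ndarray) -> np.ndarray:
    """Step (d) part 2: both ends must be homozygous non-missing calls."""
    lo, hi = 0, len(run) - 1
    while lo <= hi and not hom[run[lo]]:
        lo += 1
    while hi >= lo and not hom[run[hi]]:
        hi -= 1
    return run[lo : hi + 1]


def detect_roh(ds: GenotypeDataset, params: ROHParams | None = None) -> list[ROHSegment]:
    """Detect runs of homozygosity per sample following steps (a)–(e)."""
    params = params or ROHParams()
    chrom, pos = ds.chromosomes, ds.positions
    segments: list[ROHSegment] = []
    for c in np.unique(chrom):
        cols = np.flatnonzero(chrom == c)
        p = pos[cols]
        if np.any(np.diff(p) < 0):
            raise ValueError(f"markers on chromosome {c} are not position-sorted")
        for i, sample in enumerate(ds.samples):
            g = ds.calls[i, cols]
            het = g == 1
            miss = g == MISSING
            hom = (g == 0) | (g == 2)
            eligible = _eligible_snps(het, miss, params)
            # maximal eligible runs
            bounded = np.concatenate(([False], eligible, [False]))
            edges = np.flatnonzero(np.diff(bounded.astype(np.int8)))
            for s, e in zip(edges[::2], edges[1::2]):
                run0 = np.arange(s, e)
                for run1 in _split_on_gaps(run0, p, params.max_gap_bp):
                    if params.segment_level_caps:
                        pieces = _split_on_caps(run1, het, miss, params)
                    else:
                        pieces = [run1]
                    for piece in pieces:
                        piece = _trim(piece, hom)
                        if len(piece) < params.min_snps_in_roh:
                            continue
                        start, end = int(p[piece[0]]), int(p[piece[-1]])
                        length = end - start
                        if length < params.min_length_bp:
                            continue
                        if length / len(piece) > params.min_density_bp_per_snp:
                            continue
                        segments.append(
                            ROHSegment(
                                sample_id=sample.sample_id,
                                chromosome=int(c),
                                start_bp=start,
                                end_bp=end,
                                n_snps=len(piece),
                            )
                        )
    return segments


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

#: class edges in Mb, half-open: [1, 5), [5, 10), [10, inf)
ROH_CLASS_EDGES_MB = (1.0, 5.0, 10.0)
ROH_CLASS_LABELS = ("1~5 Mb", "5~10 Mb", ">10 Mb")


def classify_roh(
    segments: list[ROHSegment] | list[float],
) -> pd.DataFrame:
    """Per-length-class descriptive table (counts, %, mean±SD, totals).

    Accepts either segments or raw lengths in Mb.  Classes are half-open:
    a 5 Mb run belongs to 5~10, a 10 Mb run to >10.
    """
    if segments and isinstance(segments[0], ROHSegment):
        lengths = np.array([s.length_mb for s in segments])
    else:
        lengths = np.asarray(segments, dtype=np.float64)
    edges = list(ROH_CLASS_EDGES_MB) + [np.inf]
    total_n = len(lengths)
    total_len = float(lengths.sum())
    rows = []
    for label, lo, hi in zip(ROH_CLASS_LABELS, edges[:-1], edges[1:]):
        sel = lengths[(lengths >= lo) & (lengths < hi)]
        n = len(sel)
        rows.append(
            {
                "class": label,
                "count": n,
                "number_pct": 100.0 * n / total_n if total_n else 0.0,
                "mean_mb": float(sel.mean()) if n else 0.0,
                "sd_mb": float(sel.std(ddof=1)) if n > 1 else 0.0,
                "total_mb": float(sel.sum()),
                "length_pct": 100.0 * sel.sum() / total_len if total_len else 0.0,
            }
        )
    return pd.DataFrame(rows)


def class_summary_from_counts(
    counts: list[int], totals_mb: list[float]
) -> pd.DataFrame:
    """The same descriptive arithmetic from per-class counts and totals.

    Useful to check a published class table for internal consistency
    without the underlying segments; SD is not derivable and is omitted.
    """
    counts = list(counts)
    totals = list(totals_mb)
    n_all = sum(counts)
    len_all = sum(totals)
    rows = []
    for label, n, tot in zip(ROH_CLASS_LABELS, counts, totals):
        rows.append(
            {
                "class": label,
                "count": n,
                "number_pct": 100.0 * n / n_all if n_all else 0.0,
                "mean_mb": tot / n if n else 0.0,
                "total_mb": tot,
                "length_pct": 100.0 * tot / len_all if len_all else 0.0,
            }
        )
    return pd.DataFrame(rows)


def roh_summaries(
    segments: list[ROHSegment], ds: GenotypeDataset
) -> tuple[pd.Series, pd.DataFrame, float]:
    """Per-chromosome counts, per-individual count/length, mean count.

    Chromosomes and samples present in ``ds`` but without segments appear
    with zeros.  The population mean is total segments / n_samples.
    """
    chroms = sorted(np.unique(ds.chromosomes).tolist())
    per_chrom = pd.Series(0, index=chroms, dtype=int, name="n_roh")
    per_indiv = pd.DataFrame(
        {"n_roh": 0, "total_mb": 0.0}, index=ds.sample_ids
    )
    for s in segments:
        if s.chromosome in per_chrom.index:
            per_chrom[s.chromosome] += 1
        per_indiv.loc[s.sample_id, "n_roh"] += 1
        per_indiv.loc[s.sample_id, "total_mb"] += s.length_mb
    mean_count = len(segments) / ds.n_samples if ds.n_samples else 0.0
    return per_chrom, per_indiv, mean_count


def f_roh(
    segments: list[ROHSegment],
    autosome_length_kb: float = PIG_AUTOSOME_LENGTH_KB,
    sample_ids: list[str] | None = None,
) -> InbreedingResult:
    """F_ROH per individual: summed ROH length / autosomal genome length.

    ``sample_ids`` fixes the population (individuals without segments get
    F_ROH = 0 and enter the population mean); by default only individuals
    carrying segments are reported.
    """
    if autosome_length_kb <= 0:
        raise ValueError("autosome_length_kb must be positive")
    sums_kb: dict[str, float] = {sid: 0.0 for sid in (sample_ids or [])}
    for s in segments:
        if s.length_bp / 1000.0 > autosome_length_kb:
            raise ValueError(
                f"segment {s} is longer than the autosomal genome"
            )
        sums_kb[s.sample_id] = sums_kb.get(s.sample_id, 0.0) + s.length_bp / 1000.0
    per_sample = {
        sid: total / autosome_length_kb for sid, total in sums_kb.items()
    }
    bad = {k: v for k, v in per_sample.items() if v >= 1.0}
    if bad:
        raise ValueError(f"summed ROH length exceeds the genome for: {sorted(bad)}")
    mean = float(np.mean(list(per_sample.values()))) if per_sample else 0.0
    return InbreedingResult(
        f_roh_per_sample=per_sample,
        population_mean=mean,
        autosome_length_kb=autosome_length_kb,
    )


def segments_table(segments: list[ROHSegment]) -> pd.DataFrame:
    """PLINK ``.hom``-style segment table."""
    return pd.DataFrame(
        {
            "IID": [s.sample_id for s in segments],
            "CHR": [s.chromosome for s in segments],
            "POS1": [s.start_bp for s in segments],
            "POS2": [s.end_bp for s in segments],
            "KB": [s.length_bp / 1000.0 for s in segments],
            "NSNP": [s.n_snps for s in segments],
        }
    )
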