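"""Marker quality control and genetic-diversity statistics.

The QC stages mirror the usual SNP-array workflow for a conservation herd:
drop markers with low call rate, low minor-allele frequency, extreme
Hardy–Weinberg departure, and markers on the sex chromosomes.  Stages are
applied *sequentially* in that order, and each stage's removal count is
recorded on the survivors of the previous stage, so that

    n_retained = n_input_snps - (removed_call_rate + removed_maf
                                 + removed_hwe + removed_sex_chrom)

holds exactly.  The diversity summary reports the polymorphic-marker ratio
P_N = M/N, the expected heterozygosity He = mean_j 2 p_j (1 - p_j), and the
observed heterozygosity Ho = mean_j (het calls / non-missing calls).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import MISSING, SEX_CHROMOSOMES, GenotypeDataset


@dataclass(frozen=True)
class QCThresholds:
    """Marker-filter thresholds (PLINK ``--geno/--maf/--hwe`` semantics)."""

    min_call_rate: float = 0.90
    min_maf: float = 0.01
    min_hwe_p: float = 1e-6
    autosomes_only: bool = True

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_maf", "min_hwe_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class QCReport:
    n_input_snps: int
    removed_call_rate: int
    removed_maf: int
    removed_hwe: int
    removed_sex_chrom: int
    n_retained: int
    n_samples: int
    thresholds: QCThresholds = field(default_factory=QCThresholds)

    def check_arithmetic(self) -> bool:
        """Sequential-filter bookkeeping: retained = input − Σ removals."""
        removed = (
            self.removed_call_rate
            + self.removed_maf
            + self.removed_hwe
            + self.removed_sex_chrom
        )
        return self.n_retained == self.n_input_snps - removed

    def to_tsv(self) -> str:
        t = self.thresholds
        rows = [
            ("n_samples", self.n_samples),
            ("n_input_snps", self.n_input_snps),
            (f"removed_call_rate_lt_{t.min_call_rate}", self.removed_call_rate),
            (f"removed_maf_lt_{t.min_maf}", self.removed_maf),
            (f"removed_hwe_p_lt_{t.min_hwe_p}", self.removed_hwe),
            ("removed_sex_chrom", self.removed_sex_chrom),
            ("n_retained", self.n_retained),
        ]
        return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


@dataclass
class DiversitySummary:
    P_N: float
    n_polymorphic: int
    n_total: int
    He: float
    Ho: float

    def to_tsv(self) -> str:
        rows = [
            ("n_markers", self.n_total),
            ("n_polymorphic", self.n_polymorphic),
            ("P_N", f"{self.P_N:.6g}"),
            ("He", f"{self.He:.6g}"),
            ("Ho", f"{self.Ho:.6g}"),
        ]
        return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


# ---------------------------------------------------------------------------
# per-marker statistics
# ---------------------------------------------------------------------------

def marker_call_rate(ds: GenotypeDataset) -> np.ndarray:
    """Fraction of non-missing calls per marker."""
    if ds.n_samples == 0:
        raise ValueError("call rate undefined for a dataset with zero samples")
    return (ds.calls != MISSING).mean(axis=0)


def minor_allele_freq(ds: GenotypeDataset) -> np.ndarray:
    """Per-marker minor-allele frequency; NaN where no call is observed."""
    observed = ds.calls != MISSING
    n_obs = observed.sum(axis=0)
    dosage_sum = np.where(observed, ds.calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = dosage_sum / (2.0 * n_obs)
    maf = np.minimum(p, 1.0 - p)
    maf[n_obs == 0] = np.nan
    return maf


def allele_freq(ds: GenotypeDataset) -> np.ndarray:
    """Per-marker frequency of allele a2 (the counted allele); NaN if unobserved."""
    observed = ds.calls != MISSING
    n_obs = observed.sum(axis=0)
    dosage_sum = np.where(observed, ds.calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = dosage_sum / (2.0 * n_obs)
    p[n_obs == 0] = np.nan
    return p


def hwe_exact_p(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided exact Hardy–Weinberg p-value from genotype counts.

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the probabilities that are no larger than that of the observed
    configuration (the standard exact test; no mid-p adjustment).  Computed
    with the usual stable recurrence over heterozygote counts.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("need at least one genotyped individual")

    rare = 2 * min(n_hom1, n_hom2) + n_het  # rare-allele count
    # possible het counts share the parity of the rare-allele count
    het_values = range(rare % 2, min(rare, 2 * n - rare) + 1, 2)
    het_values = list(het_values)

    # unnormalised probabilities via the recurrence
    # P(het+2)/P(het) = 4 * n_hom1 * n_hom2 / ((het+2) * (het+1))
    probs = {}
    h = het_values[0]
    probs[h] = 1.0
    for h in het_values[1:]:
        h_prev = h - 2
        hom1_prev = (rare - h_prev) // 2
        hom2_prev = n - h_prev - hom1_prev
        probs[h] = probs[h_prev] * 4.0 * hom1_prev * hom2_prev / ((h - 1) * h)
    total = sum(probs.values())
    p_obs = probs[n_het] / total
    p = sum(v for v in probs.values() if v / total <= p_obs * (1.0 + 1e-12))
    return min(1.0, p / total)


def hwe_pvalues(ds: GenotypeDataset) -> np.ndarray:
    """Exact HWE p per marker, from complete genotypes only; NaN if none."""
    out = np.full(ds.n_markers, np.nan)
    cache: dict[tuple[int, int, int], float] = {}
    calls = ds.calls
    n_hom1 = (calls == 0).sum(axis=0)
    n_het = (calls == 1).sum(axis=0)
    n_hom2 = (calls == 2).sum(axis=0)
    for j in range(ds.n_markers):
        key = (int(n_hom1[j]), int(n_het[j]), int(n_hom2[j]))
        if sum(key) == 0:
            continue
        if key not in cache:
            cache[key] = hwe_exact_p(*key)
        out[j] = cache[key]
    return out


# ---------------------------------------------------------------------------
# filtering and summary
# ---------------------------------------------------------------------------

def apply_qc(
    ds: GenotypeDataset, thresholds: QCThresholds | None = None
) -> tuple[GenotypeDataset, QCReport]:
    """Filter markers sequentially: call rate → MAF → HWE → sex chromosomes.

    Each stage's removal count refers to the survivors of the previous
    stage; retained markers keep their original order.
    """
    thr = thresholds or QCThresholds()
    current = ds
    n_input = ds.n_markers

    keep = marker_call_rate(current) >= thr.min_call_rate
    removed_cr = int((~keep).sum())
    current = current.subset_markers(keep)

    if thr.min_maf > 0:
        maf = minor_allele_freq(current)
        with np.errstate(invalid="ignore"):
            # a marker with no observed call has undefined MAF and fails
            keep = np.where(np.isnan(maf), False, maf >= thr.min_maf)
    else:
        keep = np.ones(current.n_markers, dtype=bool)
    removed_maf = int((~keep).sum())
    current = current.subset_markers(keep)

    if thr.min_hwe_p > 0:
        pvals = hwe_pvalues(current)
        with np.errstate(invalid="ignore"):
            keep = ~(pvals < thr.min_hwe_p)
    else:
        keep = np.ones(current.n_markers, dtype=bool)
    removed_hwe = int((~keep).sum())
    current = current.subset_markers(keep)

    if thr.autosomes_only:
        keep = ~np.isin(current.chromosomes, SEX_CHROMOSOMES)
    else:
        keep = np.ones(current.n_markers, dtype=bool)
    removed_sex = int((~keep).sum())
    current = current.subset_markers(keep)

    report = QCReport(
        n_input_snps=n_input,
        removed_call_rate=removed_cr,
        removed_maf=removed_maf,
        removed_hwe=removed_hwe,
        removed_sex_chrom=removed_sex,
        n_retained=current.n_markers,
        n_samples=ds.n_samples,
        thresholds=thr,
    )
    assert report.check_arithmetic()
    return current, report


def diversity_summary(
    ds: GenotypeDataset, bias_corrected: bool = False
) -> DiversitySummary:
    """P_N, He and Ho for a (typically post-QC) dataset.

    ``bias_corrected`` switches He to the small-sample estimator
    2p(1-p) * 2n/(2n-1); the default is the plain plug-in ratio.
    Markers with no observed call are excluded from the He/Ho means but
    count in the P_N denominator N (they are not polymorphic).
    """
    if ds.n_markers == 0 or ds.n_samples == 0:
        raise ValueError("diversity summary needs a non-empty dataset")
    maf = minor_allele_freq(ds)
    defined = ~np.isnan(maf)
    if not defined.any():
        raise ValueError("no marker has any observed call")
    n_poly = int((maf[defined] > 0).sum())

    observed = ds.calls != MISSING
    n_obs = observed.sum(axis=0)
    p = allele_freq(ds)
    he_j = 2.0 * p[defined] * (1.0 - p[defined])
    if bias_corrected:
        two_n = 2.0 * n_obs[defined]
        he_j = he_j * two_n / np.maximum(two_n - 1.0, 1.0)
    ho_j = (ds.calls == 1).sum(axis=0)[defined] / n_obs[defined]

    return DiversitySummary(
        P_N=n_poly / ds.n_markers,
        n_polymorphic=n_poly,
        n_total=ds.n_markers,
        He=float(he_j.mean()),
        Ho=float(ho_j.mean()),
    )
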