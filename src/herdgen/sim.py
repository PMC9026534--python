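"""Pedigree gene-dropping simulator with exact identity-by-descent truth.

Founder haplotypes are drawn independently per marker from stated allele
frequencies; descendants inherit recombinant haplotypes down an explicit
pedigree.  Crossovers follow the Haldane model: the count per chromosome
is Poisson with mean ``length_Mb × cM/Mb / 100`` and breakpoints are
uniform (no interference).  Every transmitted haplotype carries its
founder-haplotype ancestry as a segment list, so the simulator can emit
the *exact* autozygous (IBD) tracts of every individual — the ground truth
against which ROH detection, F_ROH, the G matrix and family clustering
are validated.

The default configuration emulates a small closed-nucleus conservation
herd: ~8 boar-anchored families, ~200 genotyped individuals, 18 autosomes
with a few hundred SNPs each, recent inbreeding loops producing ROHs from
1 to >10 Mb, and strong LD from a small effective population size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .dataset import MISSING, GenotypeDataset, MarkerRecord, SampleRecord

DEFAULT_CHROM_LENGTH_BP = 136_000_000  # ~2.45 Gb pig autosome / 18


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

@dataclass
class PedigreeRecord:
    individual_id: str
    sire_id: str | None  # None -> founder
    dam_id: str | None
    sex: str
    family_label: str
    generation: int = 0
    expected_pedigree_F: float = 0.0


def pedigree_inbreeding(pedigree: Sequence[PedigreeRecord]) -> dict[str, float]:
    """Path-counting (tabular-kinship) inbreeding coefficient per individual.

    Founders are unrelated and non-inbred; F(i) is the kinship between i's
    parents.  Parents must precede offspring in the pedigree list.
    """
    ids = [r.individual_id for r in pedigree]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate individual_id in pedigree")
    idx = {r.individual_id: i for i, r in enumerate(pedigree)}
    n = len(pedigree)
    phi = np.zeros((n, n))
    f: dict[str, float] = {}
    for i, rec in enumerate(pedigree):
        s = rec.sire_id
        d = rec.dam_id
        if (s is None) != (d is None):
            raise ValueError(f"{rec.individual_id}: one parent known, one unknown")
        if s is None:
            fi = 0.0
        else:
            if s not in idx or d not in idx:
                raise ValueError(
                    f"{rec.individual_id}: unknown parent {s!r} or {d!r}"
                )
            if idx[s] >= i or idx[d] >= i:
                raise ValueError("parents must precede offspring in the pedigree")
            fi = phi[idx[s], idx[d]]
        f[rec.individual_id] = float(fi)
        phi[i, i] = 0.5 * (1.0 + fi)
        for j in range(i):
            if s is None:
                val = 0.0
            else:
                val = 0.5 * (phi[j, idx[s]] + phi[j, idx[d]])
            phi[i, j] = phi[j, i] = val
    return f


# ---------------------------------------------------------------------------
# founder haplotypes
# ---------------------------------------------------------------------------

@dataclass
class HaplotypePool:
    """2·n_founders haplotypes per chromosome, plus positions and frequencies."""

    n_founders: int
    chrom_length_bp: int
    positions: list[np.ndarray]  # per chromosome, sorted 1-based bp
    freqs: list[np.ndarray]  # per chromosome, frequency of allele "1"
    haplotypes: list[np.ndarray]  # per chromosome, (2F × m) uint8

    @property
    def n_chroms(self) -> int:
        return len(self.positions)


def _unique_positions(
    rng: np.random.Generator, m: int, length_bp: int
) -> np.ndarray:
    pos: np.ndarray = np.unique(rng.integers(1, length_bp + 1, size=m))
    while len(pos) < m:
        extra = rng.integers(1, length_bp + 1, size=m - len(pos))
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(pos[:m])


def simulate_founder_haplotypes(
    n_founders: int,
    n_markers_per_chrom: int,
    n_chroms: int,
    maf_distribution: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    seed: int = 0,
    chrom_length_bp: int = DEFAULT_CHROM_LENGTH_BP,
) -> HaplotypePool:
    """Draw a founder haplotype pool.

    ``maf_distribution(rng, size)`` must return minor-allele frequencies in
    (0, 0.5]; the default is Uniform(0.05, 0.5).  Which allele is the minor
    one is randomized per marker, so dosage frequencies span (0, 1).
    """
    if min(n_founders, n_markers_per_chrom, n_chroms) <= 0:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(seed)
    draw = maf_distribution or (lambda r, size: r.uniform(0.05, 0.5, size))
    positions, freqs, haps = [], [], []
    for _ in range(n_chroms):
        maf = np.asarray(draw(rng, n_markers_per_chrom), dtype=np.float64)
        if np.any((maf <= 0) | (maf > 0.5)):
            raise ValueError("maf_distribution must yield values in (0, 0.5]")
        flip = rng.random(n_markers_per_chrom) < 0.5
        p = np.where(flip, 1.0 - maf, maf)
        positions.append(_unique_positions(rng, n_markers_per_chrom, chrom_length_bp))
        freqs.append(p)
        haps.append(
            (rng.random((2 * n_founders, n_markers_per_chrom)) < p).astype(np.uint8)
        )
    return HaplotypePool(
        n_founders=n_founders,
        chrom_length_bp=chrom_length_bp,
        positions=positions,
        freqs=freqs,
        haplotypes=haps,
    )


# ---------------------------------------------------------------------------
# meiosis on ancestry-segment haplotypes
# ---------------------------------------------------------------------------

# a haplotype is a list of (start_bp, end_bp, founder_hap_index) half-open
Segs = list[tuple[int, int, int]]


def _slice_segs(segs: Segs, a: int, b: int) -> Segs:
    out = []
    for s, e, src in segs:
        if e <= a or s >= b:
            continue
        out.append((max(s, a), min(e, b), src))
    return out


def _meiosis(
    hap_a: Segs,
    hap_b: Segs,
    length_bp: int,
    cm_per_mb: float,
    rng: np.random.Generator,
) -> Segs:
    """One recombinant gamete under the Haldane model."""
    mean_x = length_bp / 1e6 * cm_per_mb / 100.0
    n_x = rng.poisson(mean_x) if mean_x > 0 else 0
    cuts = np.sort(rng.integers(1, length_bp + 1, size=n_x)) if n_x else []
    bounds = [1, *[int(c) for c in cuts], length_bp + 1]
    phase = int(rng.integers(0, 2))
    gamete: Segs = []
    for k in range(len(bounds) - 1):
        a, b = bounds[k], bounds[k + 1]
        if a >= b:
            continue
        src = hap_a if (phase + k) % 2 == 0 else hap_b
        gamete.extend(_slice_segs(src, a, b))
    # merge touching segments with the same ancestry
    merged: Segs = []
    for seg in gamete:
        if merged and merged[-1][2] == seg[2] and merged[-1][1] == seg[0]:
            merged[-1] = (merged[-1][0], seg[1], seg[2])
        else:
            merged.append(seg)
    return merged


def _ibd_intervals(hap_a: Segs, hap_b: Segs) -> list[tuple[int, int]]:
    """Intervals where both haplotypes descend from the same founder haplotype."""
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(hap_a) and j < len(hap_b):
        s1, e1, f1 = hap_a[i]
        s2, e2, f2 = hap_b[j]
        lo, hi = max(s1, s2), min(e1, e2)
        if lo < hi and f1 == f2:
            if out and out[-1][1] == lo:
                out[-1] = (out[-1][0], hi)
            else:
                out.append((lo, hi))
        if e1 <= e2:
            i += 1
        else:
            j += 1
    return out


@dataclass
class IBDSegment:
    chromosome: int
    start_bp: int
    end_bp: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass
class SimTruth:
    pedigree: list[PedigreeRecord]
    true_ibd_segments: dict[str, list[IBDSegment]]
    true_family: dict[str, str]
    sim_config: dict


def _materialize_genotypes(
    genomes: dict[str, list[tuple[Segs, Segs]]],
    pool: HaplotypePool,
    ids: list[str],
) -> np.ndarray:
    """Dosage matrix (len(ids) × total markers) from ancestry segments."""
    total_m = sum(len(p) for p in pool.positions)
    calls = np.zeros((len(ids), total_m), dtype=np.int8)
    offsets = np.cumsum([0] + [len(p) for p in pool.positions])
    for i, ind in enumerate(ids):
        for c in range(pool.n_chroms):
            pos = pool.positions[c]
            haps = pool.haplotypes[c]
            for hap_segs in genomes[ind][c]:
                for s, e, src in hap_segs:
                    lo = int(np.searchsorted(pos, s, side="left"))
                    hi = int(np.searchsorted(pos, e, side="left"))
                    if hi > lo:
                        calls[i, offsets[c] + lo : offsets[c] + hi] += haps[
                            src, lo:hi
                        ]
    return calls


def _make_dataset(
    calls: np.ndarray,
    pool: HaplotypePool,
    pedigree_by_id: dict[str, PedigreeRecord],
    ids: list[str],
    rng: np.random.Generator,
    missing_rate: float,
    error_rate: float,
) -> GenotypeDataset:
    if error_rate > 0:
        err = rng.random(calls.shape) < error_rate
        calls = np.where(err, rng.integers(0, 3, size=calls.shape), calls)
    if missing_rate > 0:
        drop = rng.random(calls.shape) < missing_rate
        calls = np.where(drop, MISSING, calls)
    markers = []
    for c in range(pool.n_chroms):
        for posn in pool.positions[c]:
            markers.append(
                MarkerRecord(
                    marker_id=f"chr{c + 1}_{posn}",
                    chromosome=c + 1,
                    position_bp=int(posn),
                    allele_a1="A",
                    allele_a2="B",
                )
            )
    samples = []
    for ind in ids:
        rec = pedigree_by_id.get(ind)
        sex = rec.sex if rec else "unknown"
        group = {"male": "boar", "female": "sow"}.get(sex)
        samples.append(SampleRecord(sample_id=ind, sex=sex, group_label=group))
    return GenotypeDataset(
        samples=samples, markers=markers, calls=calls.astype(np.int8)
    ).validate()


def gene_drop(
    pedigree: Sequence[PedigreeRecord],
    pool: HaplotypePool,
    cm_per_mb: float = 1.0,
    seed: int = 0,
    missing_rate: float = 0.0,
    error_rate: float = 0.0,
    genotyped_ids: Sequence[str] | None = None,
) -> tuple[GenotypeDataset, SimTruth]:
    """Drop founder haplotypes down a pedigree; emit genotypes + exact truth.

    Founders (records with no parents) consume pool haplotype pairs in
    pedigree order.  ``genotyped_ids`` restricts the emitted dataset (and
    IBD truth) to a subset, e.g. the final generation; the default is every
    pedigree member.
    """
    rng = np.random.default_rng(seed)
    by_id = {r.individual_id: r for r in pedigree}
    genomes: dict[str, list[tuple[Segs, Segs]]] = {}
    founder_count = 0
    L = pool.chrom_length_bp
    for rec in pedigree:
        if rec.sire_id is None:
            if founder_count >= pool.n_founders:
                raise ValueError(
                    f"haplotype pool has only {pool.n_founders} founders"
                )
            genomes[rec.individual_id] = [
                (
                    [(1, L + 1, 2 * founder_count)],
                    [(1, L + 1, 2 * founder_count + 1)],
                )
                for _ in range(pool.n_chroms)
            ]
            founder_count += 1
        else:
            for pid in (rec.sire_id, rec.dam_id):
                if pid not in genomes:
                    raise ValueError(
                        f"{rec.individual_id}: parent {pid!r} not in pedigree "
                        "(or listed after its offspring)"
                    )
            genomes[rec.individual_id] = [
                (
                    _meiosis(*genomes[rec.sire_id][c], L, cm_per_mb, rng),
                    _meiosis(*genomes[rec.dam_id][c], L, cm_per_mb, rng),
                )
                for c in range(pool.n_chroms)
            ]

    ids = list(genotyped_ids) if genotyped_ids is not None else list(genomes)
    unknown = [i for i in ids if i not in genomes]
    if unknown:
        raise ValueError(f"genotyped_ids not in pedigree: {unknown}")

    truth_ibd: dict[str, list[IBDSegment]] = {}
    for ind in ids:
        segs: list[IBDSegment] = []
        for c in range(pool.n_chroms):
            ha, hb = genomes[ind][c]
            segs.extend(
                IBDSegment(c + 1, s, e) for s, e in _ibd_intervals(ha, hb)
            )
        truth_ibd[ind] = segs

    calls = _materialize_genotypes(genomes, pool, ids)
    ds = _make_dataset(calls, pool, by_id, ids, rng, missing_rate, error_rate)
    truth = SimTruth(
        pedigree=list(pedigree),
        true_ibd_segments=truth_ibd,
        true_family={r.individual_id: r.family_label for r in pedigree},
        sim_config={
            "cm_per_mb": cm_per_mb,
            "seed": seed,
            "missing_rate": missing_rate,
            "error_rate": error_rate,
            "chrom_length_bp": pool.chrom_length_bp,
            "n_chroms": pool.n_chroms,
        },
    )
    return ds, truth


# ---------------------------------------------------------------------------
# pedigree designs
# ---------------------------------------------------------------------------

def make_conservation_pedigree(
    n_families: int = 8,
    boars_per_family: int = 4,
    sows_per_family: int = 22,
    n_generations: int = 3,
    inbred_loop_fraction: float = 0.25,
    seed: int = 0,
) -> list[PedigreeRecord]:
    """Closed-nucleus herd pedigree with boar-anchored families.

    Generation 0 holds unrelated founders per family; each later generation
    mates within the family (random boar × sow), with a stated fraction of
    matings forced between a boar and one of his full or half sisters,
    planting non-zero pedigree inbreeding.  Family labels propagate.
    """
    if min(n_families, boars_per_family, sows_per_family, n_generations) <= 0:
        raise ValueError("counts must be positive")
    if not 0.0 <= inbred_loop_fraction <= 1.0:
        raise ValueError("inbred_loop_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    pedigree: list[PedigreeRecord] = []
    prev: dict[str, tuple[list[PedigreeRecord], list[PedigreeRecord]]] = {}
    for fam in range(n_families):
        label = f"F{fam + 1}"
        boars = [
            PedigreeRecord(f"{label}_G0_B{i + 1}", None, None, "male", label, 0)
            for i in range(boars_per_family)
        ]
        sows = [
            PedigreeRecord(f"{label}_G0_S{i + 1}", None, None, "female", label, 0)
            for i in range(sows_per_family)
        ]
        pedigree += boars + sows
        prev[label] = (boars, sows)

    for gen in range(1, n_generations + 1):
        nxt: dict[str, tuple[list[PedigreeRecord], list[PedigreeRecord]]] = {}
        for fam in range(n_families):
            label = f"F{fam + 1}"
            pboars, psows = prev[label]
            boars, sows = [], []
            for i in range(boars_per_family + sows_per_family):
                sire = pboars[rng.integers(len(pboars))]
                if gen >= 2 and rng.random() < inbred_loop_fraction:
                    sisters = [
                        s
                        for s in psows
                        if s.sire_id is not None
                        and (s.sire_id == sire.sire_id or s.dam_id == sire.dam_id)
                    ]
                    dam = (
                        sisters[rng.integers(len(sisters))]
                        if sisters
                        else psows[rng.integers(len(psows))]
                    )
                else:
                    dam = psows[rng.integers(len(psows))]
                sex = "male" if i < boars_per_family else "female"
                tag = (
                    f"B{i + 1}" if sex == "male" else f"S{i - boars_per_family + 1}"
                )
                rec = PedigreeRecord(
                    f"{label}_G{gen}_{tag}",
                    sire.individual_id,
                    dam.individual_id,
                    sex,
                    label,
                    gen,
                )
                (boars if sex == "male" else sows).append(rec)
                pedigree.append(rec)
            nxt[label] = (boars, sows)
        prev = nxt

    f = pedigree_inbreeding(pedigree)
    for rec in pedigree:
        rec.expected_pedigree_F = f[rec.individual_id]
    return pedigree


def final_generation_ids(pedigree: Sequence[PedigreeRecord]) -> list[str]:
    last = max(r.generation for r in pedigree)
    return [r.individual_id for r in pedigree if r.generation == last]


def simulate_family_dataset(
    n_families: int = 8,
    boars_per_family: int = 4,
    sows_per_family: int = 22,
    n_generations: int = 3,
    inbred_loop_fraction: float = 0.25,
    n_chroms: int = 18,
    n_markers_per_chrom: int = 500,
    chrom_length_bp: int = DEFAULT_CHROM_LENGTH_BP,
    cm_per_mb: float = 1.0,
    founder_fst: float = 0.0,
    missing_rate: float = 0.02,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[GenotypeDataset, SimTruth]:
    """Study-scale herd: pedigree + gene drop, final generation genotyped.

    ``founder_fst`` > 0 draws each family's founder allele frequencies from
    a Balding–Nichols distribution around shared base frequencies, giving
    families additional between-family differentiation on top of the
    relatedness the pedigree itself creates.
    """
    rng = np.random.default_rng(seed)
    pedigree = make_conservation_pedigree(
        n_families,
        boars_per_family,
        sows_per_family,
        n_generations,
        inbred_loop_fraction,
        seed=int(rng.integers(2**31)),
    )
    founders = [r for r in pedigree if r.sire_id is None]
    pool = simulate_founder_haplotypes(
        n_founders=len(founders),
        n_markers_per_chrom=n_markers_per_chrom,
        n_chroms=n_chroms,
        seed=int(rng.integers(2**31)),
        chrom_length_bp=chrom_length_bp,
    )
    if founder_fst > 0:
        fst = founder_fst
        fam_of_founder = [r.family_label for r in founders]
        families = sorted(set(fam_of_founder))
        for c in range(n_chroms):
            base = pool.freqs[c]
            a = base * (1.0 - fst) / fst
            b = (1.0 - base) * (1.0 - fst) / fst
            fam_p = {
                fam: np.clip(rng.beta(a, b), 0.01, 0.99) for fam in families
            }
            for i, fam in enumerate(fam_of_founder):
                p = fam_p[fam]
                pool.haplotypes[c][2 * i] = (
                    rng.random(len(p)) < p
                ).astype(np.uint8)
                pool.haplotypes[c][2 * i + 1] = (
                    rng.random(len(p)) < p
                ).astype(np.uint8)

    ds, truth = gene_drop(
        pedigree,
        pool,
        cm_per_mb=cm_per_mb,
        seed=int(rng.integers(2**31)),
        missing_rate=missing_rate,
        error_rate=error_rate,
        genotyped_ids=final_generation_ids(pedigree),
    )
    truth.sim_config.update(
        n_families=n_families,
        boars_per_family=boars_per_family,
        sows_per_family=sows_per_family,
        n_generations=n_generations,
        inbred_loop_fraction=inbred_loop_fraction,
        founder_fst=founder_fst,
        n_markers_per_chrom=n_markers_per_chrom,
        master_seed=seed,
    )
    return ds, truth


def simulate_wright_fisher(
    ne_true: int,
    n_generations: int,
    n_sample: int,
    n_markers: int,
    chrom_length_bp: int = DEFAULT_CHROM_LENGTH_BP,
    seed: int = 0,
    n_chroms: int = 1,
    cm_per_mb: float = 1.0,
) -> GenotypeDataset:
    """Constant-size discrete-generation random-mating population.

    ``ne_true`` diploids per generation, two distinct parents drawn
    uniformly per offspring, recombination as in :func:`gene_drop`; the
    final generation's first ``n_sample`` individuals are genotyped at
    ``n_markers`` markers per chromosome.
    """
    if ne_true < 2:
        raise ValueError("ne_true must be >= 2")
    if not 1 <= n_sample <= ne_true:
        raise ValueError("n_sample must lie in [1, ne_true]")
    if n_generations < 1 or n_markers < 1:
        raise ValueError("n_generations and n_markers must be positive")
    rng = np.random.default_rng(seed)
    pool = simulate_founder_haplotypes(
        n_founders=ne_true,
        n_markers_per_chrom=n_markers,
        n_chroms=n_chroms,
        seed=int(rng.integers(2**31)),
        chrom_length_bp=chrom_length_bp,
    )
    L = pool.chrom_length_bp
    current: list[list[tuple[Segs, Segs]]] = [
        [
            ([(1, L + 1, 2 * i)], [(1, L + 1, 2 * i + 1)])
            for _ in range(n_chroms)
        ]
        for i in range(ne_true)
    ]
    for _ in range(n_generations):
        nxt = []
        for _ in range(ne_true):
            pa, pb = rng.choice(ne_true, size=2, replace=False)
            nxt.append(
                [
                    (
                        _meiosis(*current[pa][c], L, cm_per_mb, rng),
                        _meiosis(*current[pb][c], L, cm_per_mb, rng),
                    )
                    for c in range(n_chroms)
                ]
            )
        current = nxt

    ids = [f"WF_{i + 1}" for i in range(n_sample)]
    genomes = {ids[i]: current[i] for i in range(n_sample)}
    calls = _materialize_genotypes(genomes, pool, ids)
    return _make_dataset(calls, pool, {}, ids, rng, 0.0, 0.0)


def truth_tsv(truth: SimTruth) -> str:
    """Tab-separated dump: pedigree block, then true IBD segments."""
    lines = ["#pedigree", "individual_id\tsire_id\tdam_id\tsex\tfamily\tgeneration\tpedigree_F"]
    for r in truth.pedigree:
        lines.append(
            f"{r.individual_id}\t{r.sire_id or '0'}\t{r.dam_id or '0'}"
            f"\t{r.sex}\t{r.family_label}\t{r.generation}"
            f"\t{r.expected_pedigree_F:.6f}"
        )
    lines += ["#ibd_segments", "individual_id\tchromosome\tstart_bp\tend_bp"]
    for ind, segs in truth.true_ibd_segments.items():
        for s in segs:
            lines.append(f"{ind}\t{s.chromosome}\t{s.start_bp}\t{s.end_bp}")
    return "\n".join(lines) + "\n"


def config_echo(truth: SimTruth) -> str:
    return "".join(f"{k}={v}\n" for k, v in sorted(truth.sim_config.items()))
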