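"""In-memory SNP genotype container shared by every pipeline stage.

Genotypes are stored as allele-dosage codes counting copies of ``allele_a2``
(the second allele listed in a ``.bim`` file): 0 = hom a1/a1, 1 = het,
2 = hom a2/a2, and :data:`MISSING` (−1) for a no-call.  Marker coordinates
are 1-based physical base-pair positions, treated as opaque integers (no
assumption about the genome build).  Chromosome labels 1–18 are autosomes;
19 and 20 are reserved for the sex chromosomes of an 18-autosome karyotype
such as the pig.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

MISSING: int = -1
#: valid chromosome labels: 18 autosomes + 2 sex chromosomes
AUTOSOMES: tuple[int, ...] = tuple(range(1, 19))
SEX_CHROMOSOMES: tuple[int, ...] = (19, 20)
VALID_CHROMOSOMES: frozenset[int] = frozenset(AUTOSOMES + SEX_CHROMOSOMES)


class ValidationError(ValueError):
    """A dataset or record violates one of its declared invariants."""


@dataclass(frozen=True)
class MarkerRecord:
    """One SNP on the array."""

    marker_id: str
    chromosome: int
    position_bp: int
    allele_a1: str = "A"
    allele_a2: str = "B"

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise ValidationError(
                f"marker {self.marker_id}: position_bp must be >= 1, "
                f"got {self.position_bp}"
            )
        if self.chromosome not in VALID_CHROMOSOMES:
            raise ValidationError(
                f"marker {self.marker_id}: chromosome {self.chromosome} not in "
                f"the declared label set 1..20"
            )


@dataclass(frozen=True)
class SampleRecord:
    """One genotyped individual."""

    sample_id: str
    sex: str = "unknown"  # {male, female, unknown}
    group_label: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female", "unknown"):
            raise ValidationError(
                f"sample {self.sample_id}: sex must be male/female/unknown"
            )


@dataclass
class GenotypeDataset:
    """Samples × markers dosage matrix with its sample and marker metadata.

    ``calls`` is an ``int8`` matrix of shape (n_samples, n_markers) with
    entries in {0, 1, 2, MISSING}.  Within each chromosome markers are kept
    sorted by non-decreasing physical position (use :meth:`sorted_by_position`
    after construction from unsorted sources).
    """

    samples: list[SampleRecord]
    markers: list[MarkerRecord]
    calls: np.ndarray
    _chrom: np.ndarray | None = field(default=None, repr=False, compare=False)
    _pos: np.ndarray | None = field(default=None, repr=False, compare=False)

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    @property
    def chromosomes(self) -> np.ndarray:
        """Per-marker chromosome labels as an int array (cached)."""
        if self._chrom is None or len(self._chrom) != self.n_markers:
            self._chrom = np.array(
                [m.chromosome for m in self.markers], dtype=np.int64
            )
        return self._chrom

    @property
    def positions(self) -> np.ndarray:
        """Per-marker 1-based bp positions as an int array (cached)."""
        if self._pos is None or len(self._pos) != self.n_markers:
            self._pos = np.array(
                [m.position_bp for m in self.markers], dtype=np.int64
            )
        return self._pos

    # -- construction helpers -------------------------------------------
    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValidationError("calls must be a 2-D matrix")

    def validate(self) -> "GenotypeDataset":
        """Check every dataset invariant; return self for chaining."""
        n, m = self.calls.shape
        if n != len(self.samples) or m != len(self.markers):
            raise ValidationError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        ids = self.sample_ids
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate sample_id(s): {dupes}")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"invalid call code {self.calls[i, j]} at sample {i}, marker {j}"
            )
        chrom, pos = self.chromosomes, self.positions
        for c in np.unique(chrom):
            p = pos[chrom == c]
            if np.any(np.diff(p) < 0):
                raise ValidationError(
                    f"markers on chromosome {c} are not sorted by position"
                )
        return self

    def sorted_by_position(self) -> "GenotypeDataset":
        """Return a copy with markers stably sorted by (chromosome, position)."""
        order = np.lexsort((self.positions, self.chromosomes))
        return self.subset_markers(order)

    def subset_markers(self, index: Sequence[int] | np.ndarray) -> "GenotypeDataset":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeDataset(
            samples=list(self.samples),
            markers=[self.markers[i] for i in index],
            calls=self.calls[:, index].copy(),
        )

    def subset_samples(self, index: Sequence[int] | np.ndarray) -> "GenotypeDataset":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeDataset(
            samples=[self.samples[i] for i in index],
            markers=list(self.markers),
            calls=self.calls[index, :].copy(),
        )

    def autosomal(self) -> "GenotypeDataset":
        """Markers on autosomes (labels 1–18) only."""
        return self.subset_markers(np.isin(self.chromosomes, AUTOSOMES))

    def equals(self, other: "GenotypeDataset") -> bool:
        """Content equality on (samples, markers, calls)."""
        return (
            self.samples == other.samples
            and self.markers == other.markers
            and np.array_equal(self.calls, other.calls)
        )


def concat_markers(datasets: Iterable[GenotypeDataset]) -> GenotypeDataset:
    """Column-concatenate datasets that share an identical sample list."""
    datasets = list(datasets)
    if not datasets:
        raise ValueError("need at least one dataset")
    first = datasets[0]
    for d in datasets[1:]:
        if d.samples != first.samples:
            raise ValidationError("datasets do not share the same samples")
    return GenotypeDataset(
        samples=list(first.samples),
        markers=[m for d in datasets for m in d.markers],
        calls=np.hstack([d.calls for d in datasets]),
    )
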