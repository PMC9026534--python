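"""Genomic relationship (G) and identity-by-state (IBS) distance matrices.

G follows VanRaden's first method with allele frequencies estimated from
the sample itself (no base-population frequencies exist for a conservation
herd):

    G = Z Zᵀ / (2 Σ_j p_j (1 − p_j)),   Z_ij = x_ij − 2 p_j

Missing dosages are mean-imputed (zero after centering); monomorphic
markers carry no information and are skipped.  Off-diagonal entries
approximate twice the kinship coefficient.

The IBS distance between two individuals is the fraction of non-shared
alleles over pairwise-complete markers:

    D_ij = Σ_j |x_i − x_j| / (2 m_ij)

since a marker with dosages (x_i, x_j) shares 2 − |x_i − x_j| alleles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .dataset import MISSING, GenotypeDataset


@dataclass
class RelationshipMatrix:
    sample_ids: list[str]
    values: np.ndarray
    kind: Literal["G", "IBS_distance"]
    metadata: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def value(self, id_a: str, id_b: str) -> float:
        i = self.sample_ids.index(id_a)
        j = self.sample_ids.index(id_b)
        return float(self.values[i, j])

    def to_tsv(self) -> str:
        header = "sample_id\t" + "\t".join(self.sample_ids)
        rows = [
            sid + "\t" + "\t".join(f"{v:.6g}" for v in row)
            for sid, row in zip(self.sample_ids, self.values)
        ]
        return header + "\n" + "\n".join(rows) + "\n"


def vanraden_g(ds: GenotypeDataset) -> RelationshipMatrix:
    """VanRaden method-1 genomic relationship matrix."""
    calls = ds.calls.astype(np.float64)
    observed = calls != MISSING
    n_obs = observed.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(observed, calls, 0.0).sum(axis=0) / (2.0 * n_obs)
    usable = (n_obs > 0) & (p > 0.0) & (p < 1.0)
    if not usable.any():
        raise ValueError(
            "G matrix undefined: every marker is monomorphic or uncalled"
        )
    p = p[usable]
    z = np.where(observed[:, usable], calls[:, usable], 2.0 * p) - 2.0 * p
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    g = (z @ z.T) / denom
    return RelationshipMatrix(
        sample_ids=ds.sample_ids,
        values=g,
        kind="G",
        metadata={
            "method": "VanRaden method 1, sample allele frequencies, "
            "mean-imputed missing genotypes",
            "n_markers_used": int(usable.sum()),
        },
    )


def ibs_distance(ds: GenotypeDataset) -> RelationshipMatrix:
    """Pairwise IBS distance matrix (pairwise-complete markers).

    Raises if some pair of individuals shares no genotyped marker.
    """
    calls = ds.calls
    observed = calls != MISSING
    v = observed.astype(np.float64)
    m_ij = v @ v.T
    if np.any(m_ij == 0):
        i, j = np.argwhere(m_ij == 0)[0]
        ids = ds.sample_ids
        raise ValueError(
            f"IBS distance undefined for pair ({ids[i]}, {ids[j]}): "
            "no marker genotyped in both"
        )
    # Σ|x_i − x_j| over complete markers via dosage-class indicators:
    # Σ_{k,l} |k−l| A_k A_lᵀ with A_k the (n × m) indicator of dosage k
    a = [((calls == k) & observed).astype(np.float64) for k in (0, 1, 2)]
    diff = np.zeros_like(m_ij)
    for k in range(3):
        for l in range(3):
            w = abs(k - l)
            if w:
                diff += w * (a[k] @ a[l].T)
    d = diff / (2.0 * m_ij)
    np.fill_diagonal(d, 0.0)
    return RelationshipMatrix(
        sample_ids=ds.sample_ids,
        values=d,
        kind="IBS_distance",
        metadata={"missing_handling": "pairwise-complete deletion"},
    )
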