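"""Additive relationship matrices: genomic (GRM) and pedigree (NRM).

The GRM follows VanRaden's first method: the centred genotype cross-product
scaled by the expected heterozygosity sum, G = ZZ' / sum_k 2 p_k (1 - p_k),
with Z = M - 2p built from observed allele frequencies and missing calls
mean-imputed per SNP. The NRM is the classical tabular-method numerator
relationship matrix with founders assumed unrelated and non-inbred.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from snpwave.genotypes import GenotypeMatrix


@dataclass
class KinshipMatrix:
    sample_ids: list[str]
    matrix: np.ndarray
    kind: str  # "genomic" or "pedigree"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.sample_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("kinship matrix shape does not match sample ids")

    def is_symmetric(self, tol: float = 1e-10) -> bool:
        return bool(np.allclose(self.matrix, self.matrix.T, atol=tol))

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.matrix).min())


def _dosage_matrix(genotypes) -> tuple[np.ndarray, list[str]]:
    if isinstance(genotypes, GenotypeMatrix):
        return genotypes.dosage(impute_mean=True), list(genotypes.sample_ids)
    d = np.asarray(genotypes, dtype=float)
    if np.isnan(d).any():
        col_mean = np.nanmean(d, axis=0)
        idx = np.where(np.isnan(d))
        d = d.copy()
        d[idx] = col_mean[idx[1]]
    return d, [f"S{i}" for i in range(d.shape[0])]


def build_grm(genotypes, sample_ids: list[str] | None = None) -> KinshipMatrix:
    """VanRaden method-1 genomic relationship matrix from dosage data.

    Monomorphic SNPs carry no information and are dropped; at least one
    polymorphic SNP is required.
    """
    d, ids = _dosage_matrix(genotypes)
    if sample_ids is not None:
        ids = list(sample_ids)
    p = d.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic SNPs available for the GRM")
    z = d[:, poly] - 2.0 * p[poly]
    denom = float(np.sum(2.0 * p[poly] * (1.0 - p[poly])))
    g = z @ z.T / denom
    g = (g + g.T) / 2.0
    return KinshipMatrix(ids, g, kind="genomic")


def build_nrm(pedigree: list[tuple[str, str | None, str | None]]) -> KinshipMatrix:
    """Numerator relationship matrix by the tabular method.

    ``pedigree`` rows are (id, sire, dam); unknown parents are None, "" or
    "0". Parents must be listed before their offspring.
    """
    ids = [row[0] for row in pedigree]
    index = {}
    for i, iid in enumerate(ids):
        if iid in index:
            raise ValueError(f"duplicate pedigree id {iid!r}")
        index[iid] = i

    def parent_index(pid, child: str) -> int | None:
        if pid is None or pid in ("", "0"):
            return None
        if pid not in index:
            raise ValueError(f"parent {pid!r} of {child!r} not listed earlier")
        return index[pid]

    n = len(ids)
    a = np.zeros((n, n))
    for i, (iid, sire, dam) in enumerate(pedigree):
        s = parent_index(sire, iid)
        d = parent_index(dam, iid)
        if (s is not None and s >= i) or (d is not None and d >= i):
            raise ValueError(f"individual {iid!r} listed before its parents")
        a[i, i] = 1.0 + (0.5 * a[s, d] if s is not None and d is not None else 0.0)
        for j in range(i):
            rel = 0.0
            if s is not None:
                rel += 0.5 * a[j, s]
            if d is not None:
                rel += 0.5 * a[j, d]
            a[i, j] = a[j, i] = rel
    return KinshipMatrix(ids, a, kind="pedigree")
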