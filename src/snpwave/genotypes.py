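"""Genotype call matrices shared by the simulator, QC and GWAS modules.

Calls are stored as int8 codes: 0 = AA (hom reference), 1 = AB (het),
2 = BB (hom alternate), -1 = NoCall. The string alphabet is used only at
the TSV boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CALL_CODES = {"AA": 0, "AB": 1, "BB": 2, "NoCall": -1}
CODE_CALLS = {v: k for k, v in CALL_CODES.items()}

NOCALL = -1


@dataclass
class GenotypeMatrix:
    """samples x probesets call matrix.

    Parameters
    ----------
    sample_ids : list of str
    probeset_ids : list of str
    calls : int8 array, shape (n_samples, n_probesets), codes in {-1, 0, 1, 2}
    probeset_to_snp : optional mapping probeset id -> SNP id, for arrays where
        one SNP is interrogated by two probesets.
    sample_breed : optional mapping sample id -> breed name.
    """

    sample_ids: list[str]
    probeset_ids: list[str]
    calls: np.ndarray
    probeset_to_snp: dict[str, str] | None = None
    sample_breed: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.probeset_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.probeset_ids)} probesets"
            )
        bad = ~np.isin(self.calls, [-1, 0, 1, 2])
        if bad.any():
            raise ValueError("calls contain codes outside {AA, AB, BB, NoCall}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_probesets(self) -> int:
        return len(self.probeset_ids)

    def dosage(self, impute_mean: bool = False) -> np.ndarray:
        """Alt-allele dosage in {0, 1, 2}; NoCall as NaN or column mean."""
        d = self.calls.astype(float)
        d[d < 0] = np.nan
        if impute_mean:
            col_mean = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            idx = np.where(np.isnan(d))
            d[idx] = col_mean[idx[1]]
        return d

    def column(self, probeset_id: str) -> np.ndarray:
        return self.calls[:, self.probeset_ids.index(probeset_id)]

    def subset(self, samples: list[str] | None = None,
               probesets: list[str] | None = None) -> "GenotypeMatrix":
        samples = self.sample_ids if samples is None else samples
        probesets = self.probeset_ids if probesets is None else probesets
        si = [self.sample_ids.index(s) for s in samples]
        pi = [self.probeset_ids.index(p) for p in probesets]
        p2s = None
        if self.probeset_to_snp is not None:
            p2s = {p: self.probeset_to_snp[p] for p in probesets
                   if p in self.probeset_to_snp}
        breed = None
        if self.sample_breed is not None:
            breed = {s: self.sample_breed[s] for s in samples
                     if s in self.sample_breed}
        return GenotypeMatrix(list(samples), list(probesets),
                              self.calls[np.ix_(si, pi)], p2s, breed)

    def to_frame(self) -> pd.DataFrame:
        sym = np.vectorize(CODE_CALLS.get)(self.calls)
        return pd.DataFrame(sym, index=self.sample_ids, columns=self.probeset_ids)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def read_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        sym = df.to_numpy()
        unknown = set(sym.ravel()) - set(CALL_CODES)
        if unknown:
            raise ValueError(f"unknown call symbols {sorted(unknown)!r}")
        calls = np.vectorize(CALL_CODES.__getitem__, otypes=[np.int8])(sym)
        return cls(list(df.index), list(df.columns), calls)

    @classmethod
    def read_ped(cls, ped_path, map_path) -> "GenotypeMatrix":
        """PLINK text PED/MAP reader.

        The B allele of each SNP is the lexicographically larger of the two
        observed alleles (PED files carry no reference allele, so the coding
        is deterministic but arbitrary in sign); '0' marks a missing allele.
        """
        snp_ids = []
        with open(map_path) as fh:
            for line in fh:
                parts = line.split()
                if parts:
                    snp_ids.append(parts[1])
        m = len(snp_ids)
        sample_ids, raw = [], []
        with open(ped_path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                if len(parts) != 6 + 2 * m:
                    raise ValueError(
                        f"PED row for {parts[1] if len(parts) > 1 else '?'!r} "
                        f"has {len(parts)} fields, expected {6 + 2 * m}")
                sample_ids.append(parts[1])
                raw.append(parts[6:])
        alleles: list[set] = [set() for _ in range(m)]
        for r in raw:
            for k in range(m):
                for a in (r[2 * k], r[2 * k + 1]):
                    if a != "0":
                        alleles[k].add(a)
        b_allele = []
        for k, s in enumerate(alleles):
            if len(s) > 2:
                raise ValueError(f"SNP {snp_ids[k]!r} has {len(s)} alleles")
            b_allele.append(max(s) if s else None)
        calls = np.full((len(raw), m), NOCALL, dtype=np.int8)
        for i, r in enumerate(raw):
            for k in range(m):
                a1, a2 = r[2 * k], r[2 * k + 1]
                if a1 == "0" or a2 == "0":
                    continue
                calls[i, k] = (a1 == b_allele[k]) + (a2 == b_allele[k])
        return cls(sample_ids, snp_ids, calls)
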