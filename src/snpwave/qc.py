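"""Post-genotyping probeset quality classification.

Probesets are binned into the standard array-QC categories:
PolyHighResolution (well-called, both homozygote classes observed),
MonoHighResolution (well-called, a single homozygous cluster), NoMinorHom
(polymorphic but one homozygote class absent), CallRateBelowThreshold, and
Other. VINO (variable-intensity non-hybridizing) clusters need raw
hybridization intensities and are out of scope; the category name is
reserved for forward compatibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from snpwave.genotypes import GenotypeMatrix, NOCALL

CATEGORIES = (
    "PolyHighResolution",
    "MonoHighResolution",
    "NoMinorHom",
    "Other",
    "CallRateBelowThreshold",
    "VINO",  # reserved; requires intensity data
)

# preference order when choosing the best probeset of a SNP
_CATEGORY_RANK = {
    "PolyHighResolution": 0,
    "MonoHighResolution": 1,
    "NoMinorHom": 2,
    "Other": 3,
    "CallRateBelowThreshold": 4,
    "VINO": 5,
}


@dataclass
class ProbesetClassification:
    probeset_id: str
    category: str
    call_rate: float
    maf: float | None


def compute_call_rates(matrix: GenotypeMatrix) -> tuple[pd.Series, pd.Series]:
    """(per-sample, per-probeset) call rates: the non-NoCall fraction along
    each axis."""
    if matrix.n_samples == 0 or matrix.n_probesets == 0:
        raise ValueError("empty genotype matrix")
    called = matrix.calls != NOCALL
    sample_cr = pd.Series(called.mean(axis=1), index=matrix.sample_ids,
                          name="sample_call_rate")
    probeset_cr = pd.Series(called.mean(axis=0), index=matrix.probeset_ids,
                            name="probeset_call_rate")
    return sample_cr, probeset_cr


def _column_maf(called: np.ndarray) -> float | None:
    if len(called) == 0:
        return None
    f = called.sum() / (2 * len(called))
    return float(min(f, 1.0 - f))


def classify_probeset(
    calls: np.ndarray,
    probeset_id: str = "",
    cr_threshold: float = 0.97,
    min_minor_obs: int = 2,
) -> ProbesetClassification:
    """Classify one probeset's call column.

    Rule order: call rate below ``cr_threshold``; a single, homozygous
    genotype class; both alleles seen but one homozygote class absent; both
    homozygotes present with at least ``min_minor_obs`` minor-allele
    carriers; anything else is Other.
    """
    calls = np.asarray(calls)
    called = calls[calls != NOCALL]
    call_rate = len(called) / len(calls) if len(calls) else 0.0
    maf = _column_maf(called)
    classes = set(np.unique(called).tolist())

    if call_rate < cr_threshold:
        cat = "CallRateBelowThreshold"
    elif classes in ({0}, {2}):
        cat = "MonoHighResolution"
    elif classes in ({0, 1}, {1, 2}):
        cat = "NoMinorHom"
    elif {0, 2} <= classes:
        minor_hom = 2 if (called == 0).sum() >= (called == 2).sum() else 0
        carriers = int(((called == 1) | (called == minor_hom)).sum())
        cat = "PolyHighResolution" if carriers >= min_minor_obs else "Other"
    else:
        cat = "Other"  # e.g. hets only, or no calls at all
    return ProbesetClassification(probeset_id, cat, call_rate, maf)


def classify_matrix(matrix: GenotypeMatrix, cr_threshold: float = 0.97,
                    min_minor_obs: int = 2) -> list[ProbesetClassification]:
    return [
        classify_probeset(matrix.calls[:, i], pid, cr_threshold, min_minor_obs)
        for i, pid in enumerate(matrix.probeset_ids)
    ]


def replicate_concordance(
    matrix: GenotypeMatrix,
    replicate_pairs: list[tuple[str, str]],
) -> tuple[float | None, pd.Series]:
    """Reproducibility across replicate sample pairs.

    Returns the pooled fraction of concordant calls over all pairs (NoCall
    positions excluded from the denominator) and a per-pair series; a pair
    with no mutually called probeset is NaN and excluded from the pooled
    value.
    """
    agree = total = 0
    rows = {}
    for s1, s2 in replicate_pairs:
        for s in (s1, s2):
            if s not in matrix.sample_ids:
                raise KeyError(f"unknown sample id {s!r}")
        a = matrix.calls[matrix.sample_ids.index(s1)]
        b = matrix.calls[matrix.sample_ids.index(s2)]
        both = (a != NOCALL) & (b != NOCALL)
        n = int(both.sum())
        if n == 0:
            rows[f"{s1}|{s2}"] = np.nan
            continue
        eq = int((a[both] == b[both]).sum())
        rows[f"{s1}|{s2}"] = eq / n
        agree += eq
        total += n
    pooled = agree / total if total else None
    return pooled, pd.Series(rows, name="concordance")


def best_probeset_per_snp(
    classifications: list[ProbesetClassification],
    probeset_to_snp: dict[str, str],
) -> dict[str, ProbesetClassification]:
    """Keep one probeset per SNP: best category, then higher call rate,
    then lexicographically smaller probeset id."""
    best: dict[str, ProbesetClassification] = {}
    for cls in sorted(classifications,
                      key=lambda c: (_CATEGORY_RANK[c.category],
                                     -c.call_rate, c.probeset_id)):
        snp = probeset_to_snp.get(cls.probeset_id, cls.probeset_id)
        if snp not in best:
            best[snp] = cls
    return best


def category_report(counts: dict[str, int], denominator: int) -> pd.DataFrame:
    """Tabulate category counts as percentages of an explicit denominator
    (array-QC reports must always state what they divide by)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    rows = [
        {"category": cat, "count": int(n), "denominator": denominator,
         "percent": round(100.0 * n / denominator, 1)}
        for cat, n in counts.items()
    ]
    return pd.DataFrame(rows)


def classification_report(classifications: list[ProbesetClassification],
                          denominator: int | None = None) -> pd.DataFrame:
    counts: dict[str, int] = {}
    for cls in classifications:
        counts[cls.category] = counts.get(cls.category, 0) + 1
    return category_report(counts, denominator or len(classifications))
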