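"""Variant discovery intake: per-breed VCF loading, discovery filters,
per-breed minor allele frequencies, species-corrected reference and 71-mer
probe flank extraction.

Discovery filters retained here mirror a resequencing-based array design:
a site must be heterozygous in at least one individual of its breed, have a
variant quality above Q 10, and have no other discovered SNP within 10 bp
(probe interference). Strand-ambiguous A/T and G/C allele pairs can be
stripped separately because they need twice the probes on the array.

Coordinates are 1-based at every public surface (matching VCF); slicing into
sequences converts at the call site.
"""

from __future__ import annotations

import bisect
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from cyvcf2 import VCF

GT_HOM_REF, GT_HET, GT_HOM_ALT, GT_MISSING = 0, 1, 2, -1

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SiteRecord:
    """One biallelic SNV with per-breed genotype calls.

    ``genotypes`` maps breed name -> int array of calls coded
    0 hom-ref / 1 het / 2 hom-alt / -1 missing.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float
    genotypes: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("position must be >= 1")
        if len(self.ref) != 1 or len(self.alt) != 1 or self.ref == self.alt:
            raise ValueError(f"not a biallelic SNV: {self.ref}>{self.alt}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    def is_ambiguous(self) -> bool:
        return {self.ref.upper(), self.alt.upper()} in ({"A", "T"}, {"G", "C"})


@dataclass
class BreedSiteSummary:
    breed: str
    ref_count: int
    alt_count: int
    maf: float | None
    het_count: int

    @property
    def alt_frequency(self) -> float | None:
        total = self.ref_count + self.alt_count
        return self.alt_count / total if total else None


@dataclass
class FlankPair:
    """Two 71-mer probe flanks for one SNP, target base at position 36.

    The 5' flank is the forward-strand window; the 3' flank is its reverse
    complement (the target sits at position 36 of either, on its own
    strand). ``secondary_offsets`` are signed distances (forward-strand
    coordinates) of other discovered SNPs inside the window; the terminal
    flags mark secondary SNPs falling in the first (5') or last (3')
    25 bases of the forward-strand 71-mer.
    """

    snp_id: str
    upstream: str    # 5' flank, forward strand
    downstream: str  # 3' flank, reverse complement
    secondary_offsets: list[int]
    five_prime_flag: bool
    three_prime_flag: bool

    def __post_init__(self) -> None:
        if len(self.upstream) != 71 or len(self.downstream) != 71:
            raise ValueError("flanks must be exactly 71 bases")


class PositionIndex:
    """Sorted pooled positions of all discovered SNPs, per chromosome."""

    def __init__(self, positions: dict[str, list[int]] | None = None):
        self._pos: dict[str, list[int]] = {}
        if positions:
            for chrom, plist in positions.items():
                self._pos[chrom] = sorted(set(plist))

    @classmethod
    def from_sites(cls, sites) -> "PositionIndex":
        d: dict[str, set[int]] = {}
        for s in sites:
            d.setdefault(s.chrom, set()).add(s.pos)
        return cls({c: sorted(p) for c, p in d.items()})

    def nearest_other_distance(self, chrom: str, pos: int) -> int | None:
        """Distance to the closest *other* indexed position, or None."""
        plist = self._pos.get(chrom)
        if not plist:
            return None
        i = bisect.bisect_left(plist, pos)
        best = None
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(plist) and plist[j] != pos:
                d = abs(plist[j] - pos)
                best = d if best is None else min(best, d)
        return best

    def others_in_window(self, chrom: str, pos: int, radius: int) -> list[int]:
        plist = self._pos.get(chrom, [])
        lo = bisect.bisect_left(plist, pos - radius)
        hi = bisect.bisect_right(plist, pos + radius)
        return [p for p in plist[lo:hi] if p != pos]


def load_sites(vcf_path, breed: str) -> tuple[list[SiteRecord], Counter]:
    """Read biallelic SNVs for one breed from a VCF.

    Indels, multiallelic records and records without a QUAL value are
    skipped and tallied in the returned ledger. When several records share
    a position the highest-QUAL one wins.
    """
    ledger: Counter = Counter()
    by_pos: dict[tuple[str, int], SiteRecord] = {}
    for var in VCF(str(vcf_path)):
        if not var.is_snp or len(var.ALT) != 1:
            ledger["skipped_non_biallelic_snv"] += 1
            continue
        if var.QUAL is None:
            ledger["skipped_missing_qual"] += 1
            continue
        codes = np.array(
            [_gt_code(g) for g in var.genotypes], dtype=np.int8)
        rec = SiteRecord(var.CHROM, var.POS, var.REF, var.ALT[0],
                         float(var.QUAL), {breed: codes})
        key = rec.key
        if key in by_pos:
            ledger["duplicate_position"] += 1
            if rec.qual > by_pos[key].qual:
                by_pos[key] = rec
        else:
            by_pos[key] = rec
    return list(by_pos.values()), ledger


def _gt_code(gt) -> int:
    a, b = gt[0], gt[1]
    if a < 0 or b < 0:
        return GT_MISSING
    return a + b


def merge_breed_sites(per_breed: dict[str, list[SiteRecord]]) -> list[SiteRecord]:
    """Union per-breed site lists on (chrom, pos, ref, alt), merging the
    per-breed genotype maps; QUAL is the maximum across breeds."""
    merged: dict[tuple, SiteRecord] = {}
    for breed, sites in per_breed.items():
        for s in sites:
            key = (s.chrom, s.pos, s.ref, s.alt)
            if key not in merged:
                merged[key] = SiteRecord(s.chrom, s.pos, s.ref, s.alt,
                                         s.qual, dict(s.genotypes))
            else:
                m = merged[key]
                m.qual = max(m.qual, s.qual)
                m.genotypes.update(s.genotypes)
    return sorted(merged.values(), key=lambda s: (s.chrom, s.pos))


def filter_sites(
    sites: list[SiteRecord],
    pooled_positions: PositionIndex,
    min_quality: float = 10.0,
    min_spacing: int = 10,
) -> tuple[list[SiteRecord], list[tuple[SiteRecord, str]]]:
    """Discovery filters: heterozygous in >= 1 individual, Q strictly above
    ``min_quality``, and no other discovered SNP within ``min_spacing``
    bases (distance <= min_spacing rejects). One reason code per rejection,
    checked in that order."""
    retained, rejected = [], []
    for s in sites:
        het = any((codes == GT_HET).any() for codes in s.genotypes.values())
        if not het:
            rejected.append((s, "not_heterozygous"))
            continue
        if not s.qual > min_quality:
            rejected.append((s, "quality"))
            continue
        d = pooled_positions.nearest_other_distance(s.chrom, s.pos)
        if d is not None and d <= min_spacing:
            rejected.append((s, "spacing"))
            continue
        retained.append(s)
    return retained, rejected


def strip_ambiguous(sites: list[SiteRecord]) -> list[SiteRecord]:
    """Drop A/T and G/C SNPs (indistinguishable across strands on the array)."""
    return [s for s in sites if not s.is_ambiguous()]


def compute_breed_maf(
    sites: list[SiteRecord],
) -> list[dict[str, BreedSiteSummary]]:
    """Per-breed and combined allele summaries for each site.

    Missing genotypes are excluded from the allele counts; a breed with no
    called genotypes at a site gets maf None. The combined summary (key
    ``"combined"``) pools all breeds' calls.
    """
    out = []
    for s in sites:
        summaries: dict[str, BreedSiteSummary] = {}
        tot_ref = tot_alt = tot_het = 0
        for breed, codes in s.genotypes.items():
            called = codes[codes >= 0]
            alt = int(called.sum())
            ref = int(2 * len(called) - alt)
            het = int((called == GT_HET).sum())
            maf = None
            if len(called):
                f = alt / (ref + alt)
                maf = min(f, 1.0 - f)
            summaries[breed] = BreedSiteSummary(breed, ref, alt, maf, het)
            tot_ref += ref
            tot_alt += alt
            tot_het += het
        maf = None
        if tot_ref + tot_alt:
            f = tot_alt / (tot_ref + tot_alt)
            maf = min(f, 1.0 - f)
        summaries["combined"] = BreedSiteSummary(
            "combined", tot_ref, tot_alt, maf, tot_het)
        out.append(summaries)
    return out


def build_corrected_reference(
    reference: dict[str, str],
    sites: list[SiteRecord],
) -> dict[str, str]:
    """Substitute the alt base wherever every called individual, across all
    breeds, is homozygous alternate — producing a species-corrected
    reference. Positions already carrying the alt base are left alone
    (the operation is idempotent); a base matching neither allele is a
    hard error."""
    seqs = {c: list(seq) for c, seq in reference.items()}
    for s in sites:
        if s.chrom not in seqs:
            raise KeyError(f"unknown chromosome {s.chrom!r}")
        current = seqs[s.chrom][s.pos - 1]
        if current == s.alt:
            continue
        if current != s.ref:
            raise ValueError(
                f"reference base {current!r} at {s.chrom}:{s.pos} matches "
                f"neither ref {s.ref!r} nor alt {s.alt!r}")
        called = np.concatenate([c[c >= 0] for c in s.genotypes.values()]) \
            if s.genotypes else np.array([])
        if len(called) and (called == GT_HOM_ALT).all():
            seqs[s.chrom][s.pos - 1] = s.alt
    return {c: "".join(seq) for c, seq in seqs.items()}


TERMINAL_WINDOW = 25  # bases at either end of the 71-mer


def extract_flanks(
    corrected_reference: dict[str, str],
    site: SiteRecord,
    pooled_positions: PositionIndex,
) -> FlankPair:
    """71-mer flank pair with the target SNP at position 36 (1-based).

    Other discovered SNPs inside the window are annotated by signed offset
    from the target; offsets landing in the first or last 25 bases of the
    forward-strand 71-mer set the 5' / 3' terminal flags.
    """
    seq = corrected_reference[site.chrom]
    p0 = site.pos - 1
    if p0 < 35 or p0 + 35 >= len(seq):
        raise ValueError(f"edge_locus: {site.chrom}:{site.pos} is within "
                         "35 bases of a chromosome end")
    window = seq[p0 - 35:p0 + 36].upper()
    offsets = sorted(p - site.pos for p in
                     pooled_positions.others_in_window(site.chrom, site.pos, 35))
    five = any(off <= -(36 - TERMINAL_WINDOW) for off in offsets)
    three = any(off >= (36 - TERMINAL_WINDOW) for off in offsets)
    return FlankPair(
        snp_id=f"{site.chrom}_{site.pos}",
        upstream=window,
        downstream=reverse_complement(window),
        secondary_offsets=offsets,
        five_prime_flag=five,
        three_prime_flag=three,
    )
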