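"""Probe flank evaluation and probeset construction.

Each SNP has two candidate flanks (5' forward-strand 71-mer and 3' reverse
complement, target at position 36). A flank is classified recommended /
neutral / non-recommended from three signals: genome uniqueness of all its
16-mers, secondary polymorphisms (an interfering one within 20 nt of the
target on the flank's probe-arm side kills the flank; any other secondary
in the window demotes it to neutral), and a conversion-probability score.

The conversion probability ("p-convert") of the vendor's trained model is
proprietary; here a documented deterministic surrogate with the same
monotone behaviour stands in: it declines as GC content leaves the
[0.35, 0.55] band, as the longest homopolymer run grows past 4, as the
flank's 16-mers become less unique in the genome, and as a secondary
polymorphism approaches the target. The recommended / hard-floor thresholds
(0.6 / 0.56) act on this score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import groupby

import numpy as np

from snpwave.intake import FlankPair, reverse_complement

RECOMMENDED_P_CONVERT = 0.6
HARD_FLOOR_P_CONVERT = 0.56
INTERFERENCE_RANGE = 20  # nt from the target SNP on the probe-arm side


@dataclass(frozen=True)
class SurrogateConstants:
    """Tunable constants of the p-convert surrogate."""

    base: float = 0.9
    gc_center: float = 0.45
    gc_halfwidth: float = 0.10     # |GC - center| <= halfwidth is penalty-free
    gc_falloff: float = 0.35       # extra deviation at which the factor hits 0
    clean_homopolymer: int = 4     # runs up to this length are penalty-free
    homopolymer_penalty: float = 0.08  # per extra base of run length
    secondary_scale: float = 36.0  # distance at which a secondary stops hurting


DEFAULT_SURROGATE = SurrogateConstants()


@dataclass
class FlankEvaluation:
    side: str  # "5p" or "3p"
    category: str  # recommended | neutral | non_recommended
    reasons: list[str]
    kmer_multiplicity: int
    p_convert: float


@dataclass
class Probeset:
    probeset_id: str
    snp_id: str
    flank: str  # "5p" or "3p"
    sequence: str
    oligo_count: int
    p_convert: float
    category: str


@dataclass
class ArrayDesign:
    probesets: list[Probeset]
    n_single_flank_snps: int
    n_dual_flank_snps: int
    metadata: dict = field(default_factory=dict)

    @property
    def total_probesets(self) -> int:
        return len(self.probesets)

    @property
    def total_snps(self) -> int:
        return self.n_single_flank_snps + self.n_dual_flank_snps


def probeset_accounting(n_single_flank: int, n_dual_flank: int) -> tuple[int, int]:
    """(total probesets, total SNPs) for a design with ``n_single_flank``
    SNPs carrying one probeset and ``n_dual_flank`` SNPs carrying one
    probeset per flank."""
    return n_single_flank + 2 * n_dual_flank, n_single_flank + n_dual_flank


class KmerIndex:
    """Occurrence counts of every strand-canonical k-mer of a reference.

    A k-mer and its reverse complement are the same key, so counting is
    strand-symmetric and a palindromic k-mer is counted once per locus.
    """

    def __init__(self, reference: dict[str, str], k: int = 16):
        self.k = k
        counts: dict[str, int] = {}
        for seq in reference.values():
            s = seq.upper()
            for i in range(len(s) - k + 1):
                kmer = s[i:i + k]
                key = min(kmer, reverse_complement(kmer))
                counts[key] = counts.get(key, 0) + 1
        self._counts = counts

    def count(self, kmer: str) -> int:
        kmer = kmer.upper()
        return self._counts.get(min(kmer, reverse_complement(kmer)), 0)


def kmer_multiplicity(flank: str, reference: dict[str, str] | KmerIndex,
                      k: int = 16) -> int:
    """Maximum genome occurrence count over all k-mers of the flank,
    counting both strands."""
    if len(flank) < k:
        raise ValueError(f"flank shorter than k={k}")
    index = reference if isinstance(reference, KmerIndex) \
        else KmerIndex(reference, k=k)
    if index.k != k:
        raise ValueError("index was built with a different k")
    return max(index.count(flank[i:i + k]) for i in range(len(flank) - k + 1))


def _longest_run(seq: str) -> int:
    return max(len(list(g)) for _, g in groupby(seq))


def p_convert_surrogate(
    flank: str,
    kmer_mult: int = 1,
    secondary_offsets: list[int] | None = None,
    constants: SurrogateConstants = DEFAULT_SURROGATE,
) -> float:
    """Deterministic conversion-probability surrogate in [0, 1].

    p = base * f_gc * f_homopolymer * f_unique * f_secondary, with each
    factor in [0, 1] and monotone: more extreme GC, longer homopolymer runs,
    higher k-mer multiplicity and closer secondary polymorphisms never
    increase the score.
    """
    seq = flank.upper()
    if set(seq) - set("ACGT"):
        raise ValueError("flank contains non-ACGT characters")
    c = constants
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    excess = max(0.0, abs(gc - c.gc_center) - c.gc_halfwidth)
    f_gc = max(0.0, 1.0 - excess / c.gc_falloff)
    run = _longest_run(seq)
    f_hp = max(0.0, 1.0 - c.homopolymer_penalty * max(0, run - c.clean_homopolymer))
    f_unique = 1.0 / max(1, kmer_mult)
    f_sec = 1.0
    if secondary_offsets:
        d = min(abs(o) for o in secondary_offsets)
        f_sec = min(1.0, d / c.secondary_scale)
    return float(c.base * f_gc * f_hp * f_unique * f_sec)


def classify_flank(
    side: str,
    secondary_offsets: list[int],
    kmer_mult: int,
    p_convert: float,
) -> FlankEvaluation:
    """Category of one flank.

    Rules: an interfering secondary polymorphism within 20 nt of the target
    on this flank's probe-arm side (upstream offsets for the 5' flank,
    downstream for the 3'), or a non-unique flank, makes it non-recommended;
    secondary polymorphisms anywhere else in the window make it neutral;
    recommended requires no secondaries at all, uniqueness, and a p-convert
    strictly above 0.6.
    """
    if side not in ("5p", "3p"):
        raise ValueError("side must be '5p' or '3p'")
    arm = [o for o in secondary_offsets if (o < 0 if side == "5p" else o > 0)]
    reasons: list[str] = []
    if kmer_mult > 1:
        reasons.append("non_unique")
    if any(abs(o) <= INTERFERENCE_RANGE for o in arm):
        reasons.append("interfering_20nt")
    if reasons:
        category = "non_recommended"
    elif secondary_offsets:
        reasons.append("secondary_beyond_20nt")
        category = "neutral"
    elif p_convert <= RECOMMENDED_P_CONVERT:
        reasons.append("low_p_convert")
        category = "neutral"
    else:
        category = "recommended"
    return FlankEvaluation(side, category, reasons, kmer_mult, p_convert)


def evaluate_flank_pair(
    flanks: FlankPair,
    reference_index: KmerIndex,
    constants: SurrogateConstants = DEFAULT_SURROGATE,
) -> dict[str, FlankEvaluation]:
    """Evaluate both flanks of a SNP against a k-mer index of the genome."""
    out = {}
    for side, seq in (("5p", flanks.upstream), ("3p", flanks.downstream)):
        mult = kmer_multiplicity(seq, reference_index, k=reference_index.k)
        arm = [o for o in flanks.secondary_offsets
               if (o < 0 if side == "5p" else o > 0)]
        p = p_convert_surrogate(seq, mult, arm or None, constants)
        out[side] = classify_flank(side, flanks.secondary_offsets, mult, p)
    return out


def build_probesets(
    snp_id: str,
    flanks: FlankPair,
    evaluations: dict[str, FlankEvaluation],
    oligo_count: int = 1,
    hard_floor: float = HARD_FLOOR_P_CONVERT,
    retain_for_coverage: bool = True,
) -> tuple[list[Probeset], str | None]:
    """Zero, one or two probesets for a SNP.

    Flanks below the hard p-convert floor are discarded. With at least one
    recommended flank a single probeset is built from the recommended flank
    of highest p-convert. With none recommended, a SNP retained for genome
    coverage gets one probeset per surviving flank. Returns the probesets
    plus a drop reason when none could be built.
    """
    sequences = {"5p": flanks.upstream, "3p": flanks.downstream}
    surviving = {s: e for s, e in evaluations.items() if e.p_convert >= hard_floor}
    if not surviving:
        return [], "all_flanks_below_hard_floor"
    recommended = {s: e for s, e in surviving.items()
                   if e.category == "recommended"}

    def make(side: str, ev: FlankEvaluation) -> Probeset:
        return Probeset(
            probeset_id=f"{snp_id}.{side}",
            snp_id=snp_id,
            flank=side,
            sequence=sequences[side],
            oligo_count=oligo_count,
            p_convert=ev.p_convert,
            category=ev.category,
        )

    if recommended:
        side = max(recommended, key=lambda s: (recommended[s].p_convert, s == "5p"))
        return [make(side, recommended[side])], None
    if not retain_for_coverage:
        return [], "no_recommended_flank"
    return [make(s, e) for s, e in sorted(surviving.items())], None


def assemble_design(per_snp_probesets: dict[str, list[Probeset]],
                    metadata: dict | None = None) -> ArrayDesign:
    """Collect per-SNP probesets into an array design with its accounting."""
    probesets = [p for plist in per_snp_probesets.values() for p in plist]
    singles = sum(1 for plist in per_snp_probesets.values() if len(plist) == 1)
    duals = sum(1 for plist in per_snp_probesets.values() if len(plist) == 2)
    return ArrayDesign(probesets, singles, duals, metadata or {})
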