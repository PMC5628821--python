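"""Wave-based greedy gap-minimizing SNP panel selection.

Candidates are binned into quality "waves" (descending stringency on probe
design score, variant quality, spacing to the nearest discovered SNP, oligo
count and per-breed minor allele frequency). Within a wave the panel grows
greedily: each round picks the candidate with the highest score

    score_i = sum_j  w_j * MAF_ij * (B_ij - A_ij)
                     * (1 - |(A_ij + B_ij)/2 - P_i| / ((B_ij - A_ij)/2))

where w_j is breed j's weight, [A_ij, B_ij] is the current gap around the
candidate's position P_i between already-selected loci polymorphic in breed
j (chromosome ends included), so the score rewards filling large gaps near
their midpoint in breeds that will actually see the marker segregate.

The production engine keeps candidates in a lazily-invalidated max-heap and
rescores a candidate only when it reaches the top with a stale score;
``select_panel_oracle`` is the brute-force full-rescan reference the engine
is verified against.
"""

from __future__ import annotations

import bisect
import heapq
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml


@dataclass
class WaveCriteria:
    """One row of the wave table."""

    index: int
    min_spacing: int | None      # nearest discovered SNP must be > this (bp)
    oligos: int                  # 1 or 2, matched exactly
    design_floor: float | None   # minimum design score (p-convert)
    snp_floor: float | None      # minimum variant quality
    maf_rule: tuple              # ("per_breed", floors) | ("min_breeds", n) | ("catch_all",)

    def matches(self, cand: "CandidateSNP", breed_order: list[str]) -> bool:
        if cand.oligo_count != self.oligos:
            return False
        if self.maf_rule[0] == "catch_all":
            return True
        if self.min_spacing is not None and not cand.nearest_snp_bp > self.min_spacing:
            return False
        if self.design_floor is not None and cand.design_score < self.design_floor:
            return False
        if self.snp_floor is not None and cand.snp_score < self.snp_floor:
            return False
        kind = self.maf_rule[0]
        if kind == "per_breed":
            floors = self.maf_rule[1]
            return all(cand.maf.get(b, 0.0) > floors[i]
                       for i, b in enumerate(breed_order))
        if kind == "min_breeds":
            n = self.maf_rule[1]
            return sum(cand.maf.get(b, 0.0) > 0.0 for b in breed_order) >= n
        raise ValueError(f"unknown maf rule {kind!r}")


@dataclass
class CandidateSNP:
    snp_id: str
    chrom: str
    pos: int
    maf: dict[str, float]        # per-breed MAF
    design_score: float          # p-convert of the chosen probeset
    snp_score: float             # variant quality
    oligo_count: int = 1
    nearest_snp_bp: float = np.inf
    wave: int | None = None


@dataclass
class SelectionResult:
    selected: list[str]                      # snp ids in selection order
    per_wave_counts: dict[int, int]
    weights: dict[str, float]
    scores_at_selection: list[float]
    gap_stats: dict | None = None


def load_wave_table(path=None) -> tuple[list[WaveCriteria], dict[str, float]]:
    """Load a wave-criteria table and breed weights from YAML.

    Without ``path`` the shipped 70-wave table of the buffalo 90K design is
    used (breed weights Mediterranean 0.30, Murrah 0.30, Jaffarabadi 0.20,
    Nili-Ravi 0.20).
    """
    if path is None:
        text = resources.files("snpwave.data").joinpath(
            "axiom_buffalo_90k.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    weights = {k: float(v) for k, v in doc["breed_weights"].items()}
    breed_order = list(weights)
    waves = []
    for row in doc["waves"]:
        maf = row["maf"]
        if maf["type"] == "per_breed":
            floors = maf["floors"]
            if len(floors) != len(breed_order):
                raise ValueError("per-breed floors do not match breed weights")
            rule = ("per_breed", [float(f) for f in floors])
        elif maf["type"] == "min_breeds":
            rule = ("min_breeds", int(maf["n"]))
        elif maf["type"] == "catch_all":
            rule = ("catch_all",)
        else:
            raise ValueError(f"unknown maf rule type {maf['type']!r}")
        waves.append(WaveCriteria(
            index=int(row["wave"]),
            min_spacing=row.get("nearest_snp_bp"),
            oligos=int(row["oligos"]),
            design_floor=row.get("design_score"),
            snp_floor=row.get("snp_score"),
            maf_rule=rule,
        ))
    waves.sort(key=lambda w: w.index)
    return waves, weights


def assign_wave(cand: CandidateSNP, wave_table: list[WaveCriteria],
                breed_order: list[str]) -> int:
    """Smallest wave index whose every criterion the candidate meets;
    candidates meeting no constrained wave fall to the catch-all wave
    matching their oligo count."""
    for wave in wave_table:
        if wave.matches(cand, breed_order):
            return wave.index
    raise ValueError(
        f"candidate {cand.snp_id} matches no wave (is a catch-all wave "
        f"for oligo count {cand.oligo_count} present?)")


class GapIndex:
    """Per-breed, per-chromosome sorted positions of selected loci that are
    polymorphic in that breed; gaps are bounded by chromosome ends."""

    def __init__(self, chrom_lengths: dict[str, int], breeds: list[str]):
        self.chrom_lengths = dict(chrom_lengths)
        self.breeds = list(breeds)
        self._pos: dict[str, dict[str, list[int]]] = {
            b: {c: [] for c in chrom_lengths} for b in breeds}

    def insert(self, breed: str, chrom: str, pos: int) -> None:
        plist = self._pos[breed][chrom]
        i = bisect.bisect_left(plist, pos)
        if i == len(plist) or plist[i] != pos:
            plist.insert(i, pos)

    def positions(self, breed: str, chrom: str) -> list[int]:
        return list(self._pos[breed][chrom])

    def enclosing_gap(self, breed: str, chrom: str, pos: int) -> tuple[int, int]:
        """(A, B): nearest selected breed-polymorphic positions at or below /
        at or above ``pos``, defaulting to the chromosome ends (0, length)."""
        if chrom not in self.chrom_lengths:
            raise KeyError(f"unknown chromosome {chrom!r}")
        plist = self._pos[breed][chrom]
        i = bisect.bisect_right(plist, pos)
        a = plist[i - 1] if i > 0 else 0
        j = bisect.bisect_left(plist, pos)
        b = plist[j] if j < len(plist) else self.chrom_lengths[chrom]
        return a, b


def score_candidate(cand: CandidateSNP, index: GapIndex,
                    weights: dict[str, float]) -> float:
    """Exact evaluation of the selection score; breeds where the candidate
    is monomorphic, degenerate gaps and gap-edge positions contribute 0."""
    total = 0.0
    for breed, w in weights.items():
        maf = cand.maf.get(breed, 0.0)
        if maf <= 0.0:
            continue
        a, b = index.enclosing_gap(breed, cand.chrom, cand.pos)
        width = b - a
        if width <= 0:
            continue
        centrality = 1.0 - abs((a + b) / 2.0 - cand.pos) / (width / 2.0)
        if centrality <= 0.0:
            continue
        total += w * maf * width * centrality
    return total


def _tie_key(cand: CandidateSNP) -> tuple:
    return (cand.chrom, cand.pos, cand.snp_id)


def _insert_selected(index: GapIndex, cand: CandidateSNP) -> None:
    for breed in index.breeds:
        if cand.maf.get(breed, 0.0) > 0.0:
            index.insert(breed, cand.chrom, cand.pos)


def _group_by_wave(candidates: list[CandidateSNP],
                   wave_table: list[WaveCriteria],
                   breed_order: list[str]) -> dict[int, list[CandidateSNP]]:
    groups: dict[int, list[CandidateSNP]] = {}
    for cand in candidates:
        if cand.wave is None:
            cand.wave = assign_wave(cand, wave_table, breed_order)
        groups.setdefault(cand.wave, []).append(cand)
    return groups


def select_panel(
    candidates: list[CandidateSNP],
    wave_table: list[WaveCriteria],
    weights: dict[str, float],
    target_n: int,
    chrom_lengths: dict[str, int],
    min_score: float = 0.0,
    per_wave_cap: int | None = None,
) -> SelectionResult:
    """Greedy gap-filling selection, waves in ascending index.

    Within a wave the highest-score candidate is selected each round, its
    position enters the gap index for every breed where it is polymorphic,
    and only candidates whose cached score has gone stale are rescored (a
    lazy max-heap: scores can only decrease as gaps split, so a candidate
    whose recomputed score equals its cached one is still the maximum).
    A wave stops when exhausted, when the best score falls to ``min_score``
    or below, or at ``per_wave_cap``; selection stops at ``target_n``.
    Ties break on higher score, then chromosome, then position.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    if target_n < 1:
        raise ValueError("target_n must be >= 1")
    breed_order = list(weights)
    index = GapIndex(chrom_lengths, breed_order)
    groups = _group_by_wave(candidates, wave_table, breed_order)

    selected: list[str] = []
    scores: list[float] = []
    per_wave: dict[int, int] = {}
    for wave_idx in sorted(groups):
        if len(selected) >= target_n:
            break
        heap: list[tuple] = []
        for cand in groups[wave_idx]:
            s = score_candidate(cand, index, weights)
            heapq.heappush(heap, (-s, _tie_key(cand), cand, s))
        used = 0
        while heap and len(selected) < target_n:
            if per_wave_cap is not None and used >= per_wave_cap:
                break
            neg, key, cand, cached = heapq.heappop(heap)
            fresh = score_candidate(cand, index, weights)
            if fresh != cached:  # stale: gaps changed since scoring
                heapq.heappush(heap, (-fresh, key, cand, fresh))
                continue
            if fresh <= min_score:
                break
            selected.append(cand.snp_id)
            scores.append(fresh)
            per_wave[wave_idx] = per_wave.get(wave_idx, 0) + 1
            used += 1
            _insert_selected(index, cand)
    return SelectionResult(selected, per_wave, dict(weights), scores)


def select_panel_oracle(
    candidates: list[CandidateSNP],
    wave_table: list[WaveCriteria],
    weights: dict[str, float],
    target_n: int,
    chrom_lengths: dict[str, int],
    min_score: float = 0.0,
    per_wave_cap: int | None = None,
) -> SelectionResult:
    """Naive reference: every remaining candidate is rescanned and rescored
    each round. Semantics identical to ``select_panel``."""
    if not candidates:
        raise ValueError("empty candidate list")
    breed_order = list(weights)
    index = GapIndex(chrom_lengths, breed_order)
    groups = _group_by_wave(candidates, wave_table, breed_order)

    selected: list[str] = []
    scores: list[float] = []
    per_wave: dict[int, int] = {}
    for wave_idx in sorted(groups):
        if len(selected) >= target_n:
            break
        pool = list(groups[wave_idx])
        used = 0
        while pool and len(selected) < target_n:
            if per_wave_cap is not None and used >= per_wave_cap:
                break
            best = min(pool, key=lambda c: (-score_candidate(c, index, weights),
                                            _tie_key(c)))
            s = score_candidate(best, index, weights)
            if s <= min_score:
                break
            pool.remove(best)
            selected.append(best.snp_id)
            scores.append(s)
            per_wave[wave_idx] = per_wave.get(wave_idx, 0) + 1
            used += 1
            _insert_selected(index, best)
    return SelectionResult(selected, per_wave, dict(weights), scores)


GAP_PERCENTILES = (1, 5, 25, 50, 75, 95, 99)


def gap_statistics(positions_by_chrom: dict[str, list[int]],
                   chrom_lengths: dict[str, int] | None = None) -> dict[str, float]:
    """Min, max and {1,5,25,50,75,95,99}-percentile gap sizes between
    consecutive selected positions within chromosomes (linear-interpolation
    percentiles)."""
    gaps: list[int] = []
    for chrom, positions in positions_by_chrom.items():
        p = np.sort(np.asarray(positions))
        if len(p) >= 2:
            gaps.extend(np.diff(p).tolist())
    if not gaps:
        raise ValueError("need at least 2 selected positions on one chromosome")
    arr = np.asarray(gaps, dtype=float)
    stats = {"min": float(arr.min()), "max": float(arr.max()),
             "n_gaps": int(len(arr))}
    for q in GAP_PERCENTILES:
        stats[f"p{q}"] = float(np.percentile(arr, q))
    return stats
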