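"""variant_intake: VCF loading, discovery filters, MAFs, corrected
reference and 71-mer flank extraction."""

import numpy as np
import pytest

from snpwave import intake
from snpwave.intake import (
    FlankPair,
    PositionIndex,
    SiteRecord,
    build_corrected_reference,
    compute_breed_maf,
    extract_flanks,
    filter_sites,
    load_sites,
    merge_breed_sites,
    reverse_complement,
    strip_ambiguous,
)
from snpwave.simulate import write_vcf


def make_site(pos=1000, ref="A", alt="G", qual=50.0, chrom="chr1",
              genotypes=None):
    return SiteRecord(chrom, pos, ref, alt, qual,
                      genotypes if genotypes is not None
                      else {"b": np.array([0, 1, 2], dtype=np.int8)})


# ---------------------------------------------------------------------------
# load_sites

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=chr1,length=100000>\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
)


def write_test_vcf(path, rows):
    path.write_text(VCF_HEADER + "".join(r + "\n" for r in rows))


def test_load_sites_skips_indels(tmp_path):
    vcf = tmp_path / "a.vcf"
    write_test_vcf(vcf, [
        "chr1\t100\t.\tA\tG\t50\t.\t.\tGT\t0/1\t0/0",
        "chr1\t200\t.\tC\tT\t40\t.\t.\tGT\t1/1\t0/1",
        "chr1\t300\t.\tG\tA\t60\t.\t.\tGT\t0/0\t0/1",
        "chr1\t400\t.\tGT\tG\t30\t.\t.\tGT\t0/1\t0/0",  # indel
    ])
    sites, ledger = load_sites(vcf, "med")
    assert len(sites) == 3
    assert ledger["skipped_non_biallelic_snv"] == 1


def test_load_sites_missing_qual_logged(tmp_path):
    vcf = tmp_path / "b.vcf"
    write_test_vcf(vcf, [
        "chr1\t100\t.\tA\tG\t.\t.\t.\tGT\t0/1\t0/0",
        "chr1\t200\t.\tC\tT\t40\t.\t.\tGT\t0/1\t0/1",
    ])
    sites, ledger = load_sites(vcf, "med")
    assert len(sites) == 1
    assert ledger["skipped_missing_qual"] == 1


def test_load_sites_duplicate_position_keeps_highest_qual(tmp_path):
    vcf = tmp_path / "c.vcf"
    write_test_vcf(vcf, [
        "chr1\t100\t.\tA\tG\t20\t.\t.\tGT\t0/1\t0/0",
        "chr1\t100\t.\tA\tC\t90\t.\t.\tGT\t0/0\t0/1",
    ])
    sites, ledger = load_sites(vcf, "med")
    assert len(sites) == 1
    assert sites[0].alt == "C" and sites[0].qual == 90
    assert ledger["duplicate_position"] == 1


def test_vcf_round_trip(tmp_path, small_panel, small_genotypes, river_breeds):
    breed = river_breeds[0].name
    path = tmp_path / f"{breed}.vcf"
    write_vcf(small_panel, small_genotypes, breed, path)
    sites, ledger = load_sites(path, breed)
    assert sum(ledger.values()) == 0
    assert len(sites) == len(small_panel.sites)
    cols = [i for i, s in enumerate(small_genotypes.sample_ids)
            if small_genotypes.sample_breed[s] == breed]
    for k, (orig, got) in enumerate(zip(small_panel.sites, sites)):
        assert (got.chrom, got.pos, got.ref, got.alt) == \
               (orig.chrom, orig.pos, orig.ref, orig.alt)
        assert got.qual == pytest.approx(orig.qual, abs=0.005)
        np.testing.assert_array_equal(
            got.genotypes[breed], small_genotypes.calls[cols, k])


# ---------------------------------------------------------------------------
# filter_sites

def test_quality_nine_rejected():
    s = make_site(qual=9.0)
    retained, rejected = filter_sites([s], PositionIndex.from_sites([s]))
    assert retained == [] and rejected == [(s, "quality")]


def test_quality_exactly_ten_rejected():
    # the quality rule is strict: Q > 10
    s = make_site(qual=10.0)
    _, rejected = filter_sites([s], PositionIndex.from_sites([s]))
    assert rejected == [(s, "quality")]


def test_spacing_pair_both_rejected():
    a, b = make_site(pos=1000), make_site(pos=1008)
    retained, rejected = filter_sites([a, b], PositionIndex.from_sites([a, b]))
    assert retained == []
    assert [r for _, r in rejected] == ["spacing", "spacing"]


def test_not_heterozygous_rejected():
    s = make_site(genotypes={"b": np.array([0, 0, 0], dtype=np.int8)})
    _, rejected = filter_sites([s], PositionIndex.from_sites([s]))
    assert rejected == [(s, "not_heterozygous")]


def test_het_in_any_breed_suffices():
    s = make_site(genotypes={"b1": np.array([0, 0], dtype=np.int8),
                             "b2": np.array([0, 1], dtype=np.int8)})
    retained, _ = filter_sites([s], PositionIndex.from_sites([s]))
    assert retained == [s]


def test_ledger_counts_identity(small_panel, small_genotypes, river_breeds):
    # retained + rejected = input, with one reason per rejection
    sites = []
    for k, s in enumerate(small_panel.sites):
        genos = {}
        col = small_genotypes.calls[:, k]
        for j, b in enumerate(river_breeds):
            rows = [i for i, sid in enumerate(small_genotypes.sample_ids)
                    if small_genotypes.sample_breed[sid] == b.name]
            genos[b.name] = col[rows]
        sites.append(SiteRecord(s.chrom, s.pos, s.ref, s.alt, s.qual, genos))
    retained, rejected = filter_sites(sites, PositionIndex.from_sites(sites))
    assert len(retained) + len(rejected) == len(sites)
    assert all(r in ("not_heterozygous", "quality", "spacing")
               for _, r in rejected)


# ---------------------------------------------------------------------------
# strip_ambiguous / compute_breed_maf

@pytest.mark.parametrize("ref,alt,kept", [
    ("A", "T", False), ("G", "C", False), ("A", "G", True),
    ("C", "T", True)])
def test_strip_ambiguous(ref, alt, kept):
    s = make_site(ref=ref, alt=alt)
    assert (strip_ambiguous([s]) == [s]) is kept


def test_maf_direct_count():
    # AA, AA, AB -> alt frequency 1/6, maf 0.1667
    s = make_site(genotypes={"b": np.array([0, 0, 1], dtype=np.int8)})
    summary = compute_breed_maf([s])[0]["b"]
    assert summary.alt_count == 1 and summary.ref_count == 5
    assert summary.maf == pytest.approx(1 / 6, abs=1e-4)


def test_maf_all_het_and_all_homref():
    all_het = make_site(genotypes={"b": np.array([1, 1, 1], dtype=np.int8)})
    all_ref = make_site(genotypes={"b": np.array([0, 0, 0], dtype=np.int8)})
    assert compute_breed_maf([all_het])[0]["b"].maf == 0.5
    assert compute_breed_maf([all_ref])[0]["b"].maf == 0.0


def test_maf_missing_only_breed_is_none_and_combined_pools():
    s = make_site(genotypes={"b1": np.array([-1, -1], dtype=np.int8),
                             "b2": np.array([0, 1, 2], dtype=np.int8)})
    out = compute_breed_maf([s])[0]
    assert out["b1"].maf is None
    assert out["combined"].alt_count == 3 and out["combined"].ref_count == 3
    assert out["combined"].maf == 0.5


def test_maf_bounds(small_panel, small_genotypes, river_breeds):
    sites = []
    for k, s in enumerate(small_panel.sites[:100]):
        genos = {b.name: small_genotypes.calls[
            [i for i, sid in enumerate(small_genotypes.sample_ids)
             if small_genotypes.sample_breed[sid] == b.name], k]
            for b in river_breeds}
        sites.append(SiteRecord(s.chrom, s.pos, s.ref, s.alt, s.qual, genos))
    for summaries in compute_breed_maf(sites):
        for v in summaries.values():
            if v.maf is not None:
                assert 0.0 <= v.maf <= 0.5


# ---------------------------------------------------------------------------
# build_corrected_reference

def _ref():
    return {"chr1": "AAAAAAAAAA"}


def test_hom_alt_everywhere_substituted():
    s = make_site(pos=3, ref="A", alt="G", chrom="chr1",
                  genotypes={"b1": np.array([2, 2], dtype=np.int8),
                             "b2": np.array([2, -1], dtype=np.int8)})
    out = build_corrected_reference(_ref(), [s])
    assert out["chr1"] == "AAGAAAAAAA"


def test_het_anywhere_leaves_base():
    s = make_site(pos=3, ref="A", alt="G", chrom="chr1",
                  genotypes={"b": np.array([2, 1], dtype=np.int8)})
    assert build_corrected_reference(_ref(), [s]) == _ref()


def test_lengths_unchanged_and_idempotent():
    s = make_site(pos=5, ref="A", alt="C", chrom="chr1",
                  genotypes={"b": np.array([2, 2], dtype=np.int8)})
    once = build_corrected_reference(_ref(), [s])
    twice = build_corrected_reference(once, [s])
    assert len(once["chr1"]) == 10
    assert once == twice


def test_mismatch_is_hard_error():
    s = make_site(pos=2, ref="C", alt="G", chrom="chr1")
    with pytest.raises(ValueError, match="chr1:2"):
        build_corrected_reference(_ref(), [s])


# ---------------------------------------------------------------------------
# extract_flanks

def _long_ref(n=2000, seed=0):
    rng = np.random.default_rng(seed)
    return {"chr1": "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))}


def test_isolated_site_flanks():
    ref = _long_ref()
    pos = 500
    s = SiteRecord("chr1", pos, ref["chr1"][pos - 1],
                   "A" if ref["chr1"][pos - 1] != "A" else "C", 50.0)
    fp = extract_flanks(ref, s, PositionIndex.from_sites([s]))
    assert len(fp.upstream) == len(fp.downstream) == 71
    assert fp.upstream == ref["chr1"][pos - 36:pos + 35]
    assert fp.upstream[35] == ref["chr1"][pos - 1]  # target at position 36
    assert fp.downstream == reverse_complement(fp.upstream)
    assert fp.secondary_offsets == []
    assert not fp.five_prime_flag and not fp.three_prime_flag


def test_secondary_at_plus_30_sets_three_prime_flag():
    ref = _long_ref()
    s = SiteRecord("chr1", 500, ref["chr1"][499], "A"
                   if ref["chr1"][499] != "A" else "C", 50.0)
    idx = PositionIndex({"chr1": [500, 530]})
    fp = extract_flanks(ref, s, idx)
    assert fp.secondary_offsets == [30]
    assert fp.three_prime_flag and not fp.five_prime_flag


def test_secondary_at_minus_12_sets_five_prime_flag():
    ref = _long_ref()
    s = SiteRecord("chr1", 500, ref["chr1"][499], "A"
                   if ref["chr1"][499] != "A" else "C", 50.0)
    fp = extract_flanks(ref, s, PositionIndex({"chr1": [488, 500]}))
    assert fp.secondary_offsets == [-12]
    assert fp.five_prime_flag and not fp.three_prime_flag


def test_secondary_outside_window_ignored():
    ref = _long_ref()
    s = SiteRecord("chr1", 500, ref["chr1"][499], "A"
                   if ref["chr1"][499] != "A" else "C", 50.0)
    fp = extract_flanks(ref, s, PositionIndex({"chr1": [500, 560]}))
    assert fp.secondary_offsets == []


def test_edge_locus_error():
    ref = _long_ref()
    s = SiteRecord("chr1", 20, ref["chr1"][19], "A"
                   if ref["chr1"][19] != "A" else "C", 50.0)
    with pytest.raises(ValueError, match="edge_locus"):
        extract_flanks(ref, s, PositionIndex.from_sites([s]))


def test_merge_breed_sites_unions_and_max_quals():
    a = make_site(genotypes={"b1": np.array([0, 1], dtype=np.int8)}, qual=30)
    b = make_site(genotypes={"b2": np.array([2, 1], dtype=np.int8)}, qual=70)
    c = make_site(pos=2000, genotypes={"b2": np.array([1, 1], dtype=np.int8)})
    merged = merge_breed_sites({"b1": [a], "b2": [b, c]})
    assert len(merged) == 2
    first = merged[0]
    assert set(first.genotypes) == {"b1", "b2"} and first.qual == 70
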