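"""Filter cascade, mutation typing and coding-effect annotation.

The cascade is checked against an independent brute-force oracle that
literally enumerates the printed rules over random count matrices.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gutevolve.io_formats import GeneAnnotation, PipelineConfig, \
    ReferenceGenome
from gutevolve.variant_core import (AMBIGUOUS, ANCESTRAL, DERIVED,
                                    MUTATION_CLASSES, AlleleCountMatrix,
                                    SnpRecord, annotate_coding_effect,
                                    call_site_genotype,
                                    classify_mutation_type,
                                    filter_candidate_sites)

BASES = "ACGT"


def _cell(base, fwd, rev, quality=30.0, extra=None):
    c = np.zeros((4, 2), dtype=np.int64)
    c[BASES.index(base)] = (fwd, rev)
    if extra:
        for b, f, r in extra:
            c[BASES.index(b)] += (f, r)
    return c, quality


class TestCallSiteGenotype:
    def test_clean_pass(self):
        c, q = _cell("G", 8, 8)
        res = call_site_genotype(c, q)
        assert res.passed and res.allele == "G"

    def test_strand_depth_failure(self):
        c, q = _cell("G", 6, 20)
        res = call_site_genotype(c, q)
        assert not res.passed and "strand_depth" in res.fail_reasons

    def test_major_allele_frequency_failure(self):
        # 17 G / 3 A over 10+10 stranded reads: 85% < 90%
        c, q = _cell("G", 8, 9, extra=[("A", 2, 1)])
        assert c.sum() == 20 and c[BASES.index("G")].sum() == 17
        res = call_site_genotype(c, q)
        assert not res.passed
        assert res.fail_reasons == ("major_allele_frequency",)

    def test_quality_boundary_is_strict(self):
        c, _ = _cell("G", 8, 8)
        assert call_site_genotype(c, 59.999).passed
        res = call_site_genotype(c, 60.0)  # "less than 60" passes
        assert not res.passed and "quality" in res.fail_reasons

    def test_missing_cell(self):
        c, q = _cell("G", 8, 8)
        res = call_site_genotype(c, q, missing=True)
        assert not res.passed and res.fail_reasons == ("missing",)

    def test_fifty_fifty_tie_gives_no_allele(self):
        c, q = _cell("G", 10, 10, extra=[("A", 10, 10)])
        res = call_site_genotype(c, q)
        assert not res.passed and res.allele is None


# ---------------------------------------------------------------------------
# brute-force oracle for the site-retention cascade
# ---------------------------------------------------------------------------

def brute_force_filter(matrix, ancestral, cfg):
    """Literal enumeration of the printed rules, independent of the
    implementation under test: per-cell quality/strand/MAF filters, all
    isolate pairs for discordance, median coverage >= 10, and the 33%
    isolate-failure rule."""
    retained = []
    n = len(matrix.isolates)
    for i, (rep, pos) in enumerate(matrix.sites):
        cells = []
        for j in range(n):
            if matrix.missing[i, j]:
                cells.append((None, False))
                continue
            counts = matrix.counts[i, j]
            per_base = counts.sum(axis=1)
            total = per_base.sum()
            ok = matrix.site_quality[i, j] < cfg.max_site_quality
            ok &= counts[:, 0].sum() >= cfg.min_strand_depth
            ok &= counts[:, 1].sum() >= cfg.min_strand_depth
            allele = None
            if total > 0:
                top = per_base.max()
                ok &= top / total >= cfg.min_major_af
                winners = [b for k, b in enumerate(BASES)
                           if per_base[k] == top]
                allele = winners[0] if len(winners) == 1 else None
                ok &= allele is not None
            else:
                ok = False
            cells.append((allele, bool(ok)))
        n_fail = sum(1 for _, ok in cells if not ok)
        if n_fail / n >= cfg.fail_num / cfg.fail_den:
            continue
        coverages = sorted(matrix.counts[i, j].sum() for j in range(n))
        mid = n // 2
        med = (coverages[mid] if n % 2 else
               (coverages[mid - 1] + coverages[mid]) / 2)
        if med < cfg.min_median_coverage:
            continue
        discordant = any(
            a[1] and b[1] and a[0] != b[0]
            for a, b in itertools.combinations(cells, 2))
        if not discordant:
            continue
        ref = ancestral.base_at(rep, pos)
        if not any(ok and al != ref for al, ok in cells):
            continue
        retained.append((rep, pos))
    return retained


def _random_matrix(rng, n_iso=8, n_sites=12):
    sites = [("chr", int(p)) for p in
             sorted(rng.choice(np.arange(1, 200), size=n_sites,
                               replace=False))]
    counts = np.zeros((n_sites, n_iso, 4, 2), dtype=np.int64)
    quality = np.zeros((n_sites, n_iso))
    missing = np.zeros((n_sites, n_iso), dtype=bool)
    for i in range(n_sites):
        for j in range(n_iso):
            if rng.random() < 0.08:
                missing[i, j] = True
                quality[i, j] = np.nan
                continue
            depth = int(rng.integers(0, 40))
            major = BASES[rng.integers(0, 4)]
            minor = BASES[rng.integers(0, 4)]
            n_minor = int(rng.binomial(depth, rng.choice([0.0, 0.05, 0.3])))
            per_base = np.zeros(4, dtype=np.int64)
            per_base[BASES.index(major)] += depth - n_minor
            per_base[BASES.index(minor)] += n_minor
            fwd = rng.binomial(per_base, 0.5)
            counts[i, j, :, 0] = fwd
            counts[i, j, :, 1] = per_base - fwd
            quality[i, j] = rng.uniform(20, 100)  # straddles the 60 cutoff
    return AlleleCountMatrix(sites=sites, isolates=[f"i{j}" for j in range(n_iso)],
                             counts=counts, site_quality=quality,
                             missing=missing)


@pytest.fixture(scope="module")
def toy_reference():
    rng = np.random.default_rng(99)
    seq = "".join(np.array(list(BASES))[rng.integers(0, 4, 200)])
    return ReferenceGenome(replicons={"chr": seq})


def test_filter_matches_brute_force_on_random_matrices(toy_reference):
    cfg = PipelineConfig()
    rng = np.random.default_rng(2024)
    for _ in range(200):
        m = _random_matrix(rng)
        snps, gm, audit = filter_candidate_sites(m, toy_reference, cfg)
        got = [(s.replicon_id, s.pos) for s in snps]
        expected = brute_force_filter(m, toy_reference, cfg)
        assert got == sorted(expected)


def test_filter_is_order_independent(toy_reference):
    rng = np.random.default_rng(7)
    m = _random_matrix(rng)
    snps_a, _, _ = filter_candidate_sites(m, toy_reference)
    perm = rng.permutation(len(m.sites))
    iperm = rng.permutation(len(m.isolates))
    shuffled = AlleleCountMatrix(
        sites=[m.sites[k] for k in perm],
        isolates=[m.isolates[k] for k in iperm],
        counts=m.counts[perm][:, iperm],
        site_quality=m.site_quality[perm][:, iperm],
        missing=m.missing[perm][:, iperm])
    snps_b, _, _ = filter_candidate_sites(shuffled, toy_reference)
    assert [(s.replicon_id, s.pos, s.alt_allele) for s in snps_a] == \
           [(s.replicon_id, s.pos, s.alt_allele) for s in snps_b]


def test_retained_sites_have_discordant_passing_pair(toy_reference):
    rng = np.random.default_rng(11)
    for _ in range(20):
        m = _random_matrix(rng)
        snps, gm, _ = filter_candidate_sites(m, toy_reference)
        for k, s in enumerate(snps):
            # the derived allele is always observed, and the passing calls
            # span at least two distinct alleles (discordance)
            col = gm.calls[:, k]
            assert (col == DERIVED).any()
            i = m.sites.index((s.replicon_id, s.pos))
            passing = {c.allele for j in range(len(m.isolates))
                       for c in [call_site_genotype(
                           m.counts[i, j], m.site_quality[i, j],
                           bool(m.missing[i, j]))] if c.passed}
            assert len(passing) >= 2


def test_failure_fraction_boundary(toy_reference):
    """10 isolates with 4 failing (40% >= 33%) discards the site."""
    n = 10
    counts = np.zeros((1, n, 4, 2), dtype=np.int64)
    quality = np.full((1, n), 30.0)
    missing = np.zeros((1, n), dtype=bool)
    ref = toy_reference.base_at("chr", 5)
    alt = "A" if ref != "A" else "C"
    for j in range(n):
        base = alt if j < 5 else ref
        counts[0, j, BASES.index(base)] = (10, 10)
    quality[0, :4] = 80.0  # 4 quality failures
    m = AlleleCountMatrix(sites=[("chr", 5)],
                          isolates=[f"i{j}" for j in range(n)],
                          counts=counts, site_quality=quality, missing=missing)
    snps, _, audit = filter_candidate_sites(m, toy_reference)
    assert snps == []
    assert "isolate_failure_fraction" in audit[0]["reasons"]
    # 3 failures (30% < 33%) keeps it
    quality[0, :4] = 30.0
    quality[0, :3] = 80.0
    snps, _, _ = filter_candidate_sites(
        AlleleCountMatrix(sites=[("chr", 5)], isolates=m.isolates,
                          counts=counts, site_quality=quality,
                          missing=missing), toy_reference)
    assert len(snps) == 1


def test_all_ancestral_sites_yield_no_snps(toy_reference):
    n = 6
    counts = np.zeros((2, n, 4, 2), dtype=np.int64)
    for i, pos in enumerate((3, 8)):
        ref = toy_reference.base_at("chr", pos)
        counts[i, :, BASES.index(ref)] = (12, 12)
    m = AlleleCountMatrix(sites=[("chr", 3), ("chr", 8)],
                          isolates=[f"i{j}" for j in range(n)],
                          counts=counts, site_quality=np.full((2, n), 20.0),
                          missing=np.zeros((2, n), dtype=bool))
    snps, _, audit = filter_candidate_sites(m, toy_reference)
    assert snps == []
    assert all("no_discordant_pair" in a["reasons"] for a in audit)


def test_fewer_than_two_isolates_rejected(toy_reference):
    m = AlleleCountMatrix(sites=[("chr", 1)], isolates=["only"],
                          counts=np.zeros((1, 1, 4, 2), dtype=np.int64),
                          site_quality=np.full((1, 1), 20.0),
                          missing=np.zeros((1, 1), dtype=bool))
    with pytest.raises(ValueError, match="at least 2"):
        filter_candidate_sites(m, toy_reference)


# ---------------------------------------------------------------------------
# mutation typing
# ---------------------------------------------------------------------------

class TestClassifyMutationType:
    def test_example_from_confirmed_table(self):
        assert classify_mutation_type("C", "A") == "G:C>T:A"

    def test_strand_symmetry(self):
        assert classify_mutation_type("T", "C") == \
            classify_mutation_type("A", "G") == "A:T>G:C"

    @given(st.sampled_from("ACGT"), st.sampled_from("ACGT"))
    def test_total_strand_symmetric_partition(self, ref, alt):
        comp = dict(zip("ACGT", "TGCA"))
        if ref == alt:
            with pytest.raises(ValueError):
                classify_mutation_type(ref, alt)
        else:
            cls = classify_mutation_type(ref, alt)
            assert cls in MUTATION_CLASSES
            assert cls == classify_mutation_type(comp[ref], comp[alt])

    def test_confirmed_table_tally(self, table1_snps):
        tally = {c: 0 for c in MUTATION_CLASSES}
        for s in table1_snps:
            tally[classify_mutation_type(s.ref_allele, s.alt_allele)] += 1
        assert tally == {"A:T>G:C": 8, "A:T>C:G": 7, "G:C>T:A": 5,
                         "G:C>A:T": 2, "A:T>T:A": 0, "G:C>C:G": 0}


# ---------------------------------------------------------------------------
# coding effect
# ---------------------------------------------------------------------------

@pytest.fixture
def toy_gene_genome():
    # + strand gene ATG GCT TAA at 1..9, - strand copy on a second replicon
    fwd = "ATGGCTTAA" + "ACGTAC"
    from Bio.Seq import Seq
    rev = "TTTT" + str(Seq("ATGGCTTAA").reverse_complement()) + "GG"
    return ReferenceGenome(
        replicons={"c1": fwd, "c2": rev},
        annotations=[GeneAnnotation("gp", "c1", 1, 9, "+", "toy"),
                     GeneAnnotation("gm", "c2", 5, 13, "-", "toy")])


def _snp(rep, pos, ref, alt):
    return SnpRecord(snp_id=f"s{pos}", replicon_id=rep, pos=pos,
                     ref_allele=ref, alt_allele=alt)


def test_synonymous_third_position(toy_gene_genome):
    out = annotate_coding_effect(_snp("c1", 6, "T", "C"), toy_gene_genome)
    assert out.coding_effect == "synonymous" and out.aa_change == "A2A"


def test_nonsynonymous_first_position(toy_gene_genome):
    out = annotate_coding_effect(_snp("c1", 4, "G", "A"), toy_gene_genome)
    assert out.coding_effect == "nonsynonymous" and out.aa_change == "A2T"


def test_minus_strand_gene(toy_gene_genome):
    # genomic position 8 on c2 is the third base of codon 2 (gene base T)
    ref = toy_gene_genome.base_at("c2", 8)
    alt = "G" if ref != "G" else "C"
    out = annotate_coding_effect(_snp("c2", 8, ref, alt), toy_gene_genome)
    assert out.gene_id == "gm"
    assert out.aa_change[1] == "2"  # codon 2 regardless of strand


def test_intergenic_snp(toy_gene_genome):
    out = annotate_coding_effect(_snp("c1", 12, "G", "T"), toy_gene_genome)
    assert out.coding_effect == "intergenic" and out.gene_id is None


def test_partial_codon_gene_warns_and_is_ambiguous():
    g = ReferenceGenome(replicons={"c": "ATGGCTTA"},
                        annotations=[GeneAnnotation("g1", "c", 1, 8, "+", "")])
    with pytest.warns(UserWarning, match="multiple of 3"):
        out = annotate_coding_effect(_snp("c", 4, "G", "A"), g)
    assert out.coding_effect == "ambiguous"
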