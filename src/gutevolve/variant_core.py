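"""Isolate SNP calling: the multi-isolate filter cascade, six-class mutation
typing, and coding-effect annotation.

The cascade evaluates every candidate site against the study's printed rules:

* a per-cell (isolate at site) call passes when its quality score is below the
  threshold (default 60), at least 7 reads aligned to each strand, and the
  major allele holds at least 90% of the reads;
* a site is retained when at least one pair of passing isolates is discordant
  on the called base, the median total coverage across all isolates is at
  least 10 reads, and fewer than one third of isolates fail the per-cell
  filters (the "33% or more" rule, compared exactly as a rational so the
  boundary never depends on floating-point rounding).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from Bio.Seq import Seq

from .io_formats import PipelineConfig, ReferenceGenome

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}

# genotype call codes
ANCESTRAL, DERIVED, AMBIGUOUS = 0, 1, -1

#: the six strand-symmetric substitution classes
MUTATION_CLASSES = ("A:T>G:C", "G:C>A:T", "A:T>C:G",
                    "G:C>T:A", "A:T>T:A", "G:C>C:G")

_CLASS_OF = {
    ("A", "G"): "A:T>G:C", ("T", "C"): "A:T>G:C",
    ("G", "A"): "G:C>A:T", ("C", "T"): "G:C>A:T",
    ("A", "C"): "A:T>C:G", ("T", "G"): "A:T>C:G",
    ("G", "T"): "G:C>T:A", ("C", "A"): "G:C>T:A",
    ("A", "T"): "A:T>T:A", ("T", "A"): "A:T>T:A",
    ("G", "C"): "G:C>C:G", ("C", "G"): "G:C>C:G",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class SnpRecord:
    """One confirmed single-nucleotide variant against the ancestral genome."""

    snp_id: str
    replicon_id: str
    pos: int                      # 1-based
    ref_allele: str
    alt_allele: str
    gene_id: Optional[str] = None          # None = intergenic
    mutation_class: Optional[str] = None
    coding_effect: Optional[str] = None    # synonymous/nonsynonymous/intergenic
    aa_change: Optional[str] = None        # e.g. "A2T", 1-based protein position
    gene_name: Optional[str] = None
    product: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.snp_id}: ref == alt ({self.ref_allele})")


@dataclass
class AlleleCountMatrix:
    """Dense (site x isolate) stranded base counts with per-cell quality.

    ``counts`` has shape (n_sites, n_isolates, 4 bases, 2 strands); missing
    cells carry zero counts, NaN quality and ``missing=True``.
    """

    sites: list[tuple[str, int]]
    isolates: list[str]
    counts: np.ndarray
    site_quality: np.ndarray
    missing: np.ndarray

    def __post_init__(self) -> None:
        n_s, n_i = len(self.sites), len(self.isolates)
        if self.counts.shape != (n_s, n_i, 4, 2):
            raise ValueError(f"counts shape {self.counts.shape} inconsistent "
                             f"with {n_s} sites x {n_i} isolates")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if self.site_quality.shape != (n_s, n_i):
            raise ValueError("site_quality shape inconsistent")
        if self.missing.shape != (n_s, n_i):
            raise ValueError("missing mask shape inconsistent")

    def coverage(self) -> np.ndarray:
        """Total reads per (site, isolate), zero where missing."""
        return self.counts.sum(axis=(2, 3))


@dataclass
class GenotypeMatrix:
    """Isolates x SNPs calls: 0 ancestral, 1 derived, -1 ambiguous."""

    isolates: list[str]
    snps: list[SnpRecord]
    calls: np.ndarray  # int8, shape (n_isolates, n_snps)

    def __post_init__(self) -> None:
        if self.calls.shape != (len(self.isolates), len(self.snps)):
            raise ValueError("calls shape inconsistent")
        if not np.isin(self.calls, [ANCESTRAL, DERIVED, AMBIGUOUS]).all():
            raise ValueError("calls must be 0, 1 or -1")

    def derived_isolates(self, snp_index: int) -> frozenset[str]:
        """Ids of isolates unambiguously carrying the derived allele."""
        mask = self.calls[:, snp_index] == DERIVED
        return frozenset(np.asarray(self.isolates, dtype=object)[mask])

    def column(self, snp_id: str) -> int:
        for j, s in enumerate(self.snps):
            if s.snp_id == snp_id:
                return j
        raise KeyError(snp_id)


@dataclass(frozen=True)
class SiteCall:
    """Result of the per-cell filter at one (site, isolate)."""

    allele: Optional[str]
    passed: bool
    fail_reasons: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# per-cell call
# ---------------------------------------------------------------------------

def call_site_genotype(counts: np.ndarray, quality: float,
                       missing: bool = False,
                       config: PipelineConfig | None = None) -> SiteCall:
    """Apply the per-isolate filters to one cell's stranded counts.

    Returns the majority allele together with pass/fail and the set of
    violated criteria.  A 50/50 tie for the majority allele yields no allele
    (the 90% major-allele rule can never pass a tie).
    """
    cfg = config or PipelineConfig()
    if missing:
        return SiteCall(allele=None, passed=False, fail_reasons=("missing",))
    counts = np.asarray(counts)
    reasons: list[str] = []
    if not (quality < cfg.max_site_quality):
        reasons.append("quality")
    fwd, rev = counts[:, 0].sum(), counts[:, 1].sum()
    if fwd < cfg.min_strand_depth or rev < cfg.min_strand_depth:
        reasons.append("strand_depth")
    per_base = counts.sum(axis=1)
    total = per_base.sum()
    allele: Optional[str] = None
    if total == 0:
        reasons.append("major_allele_frequency")
    else:
        top = per_base.max()
        winners = [BASES[i] for i in range(4) if per_base[i] == top]
        if len(winners) == 1:
            allele = winners[0]
        # a tie gives no unambiguous call; MAF below also fails (top/total <= .5)
        if top / total < cfg.min_major_af:
            reasons.append("major_allele_frequency")
    passed = not reasons
    return SiteCall(allele=allele if passed else allele,
                    passed=passed, fail_reasons=tuple(reasons))


# ---------------------------------------------------------------------------
# filter cascade over candidate sites
# ---------------------------------------------------------------------------

def filter_candidate_sites(matrix: AlleleCountMatrix,
                           ancestral: ReferenceGenome,
                           config: PipelineConfig | None = None,
                           ) -> tuple[list[SnpRecord], GenotypeMatrix,
                                      list[dict]]:
    """Run the site-retention cascade over all candidate positions.

    Returns (SNP records sorted by coordinate, genotype matrix, audit log).
    The audit log holds one entry per input site with the retention decision
    and every rejection reason.  The retained set is independent of the order
    in which sites or isolates are presented.
    """
    cfg = config or PipelineConfig()
    n_iso = len(matrix.isolates)
    if n_iso < 2:
        raise ValueError("filter cascade needs at least 2 isolates")

    site_order = sorted(range(len(matrix.sites)), key=lambda i: matrix.sites[i])

    snps: list[SnpRecord] = []
    audit: list[dict] = []
    geno_cols: list[np.ndarray] = []
    coverage = matrix.coverage()

    for i in site_order:
        rep, pos = matrix.sites[i]
        ref = ancestral.base_at(rep, pos)
        qualities = matrix.site_quality[i]
        if cfg.site_level_quality:
            observed = qualities[~matrix.missing[i]]
            site_q = float(np.median(observed)) if observed.size else np.inf
        calls = []
        for j in range(n_iso):
            q = site_q if cfg.site_level_quality else qualities[j]
            calls.append(call_site_genotype(matrix.counts[i, j], q,
                                            bool(matrix.missing[i, j]), cfg))
        n_fail = sum(not c.passed for c in calls)
        reasons: list[str] = []
        # (iii) exact rational comparison: fail fraction >= fail_num/fail_den
        if n_fail * cfg.fail_den >= n_iso * cfg.fail_num:
            reasons.append("isolate_failure_fraction")
        # (ii) median coverage across all isolates (missing contribute 0)
        med = float(np.median(coverage[i]))
        if med < cfg.min_median_coverage:
            reasons.append("median_coverage")
        # (i) at least one discordant pair of passing calls
        passing_alleles = [c.allele for c in calls if c.passed]
        if len(set(passing_alleles)) < 2:
            reasons.append("no_discordant_pair")

        entry = {"replicon": rep, "pos": pos, "retained": not reasons,
                 "reasons": tuple(reasons), "n_fail": n_fail,
                 "median_coverage": med}
        if reasons:
            audit.append(entry)
            continue

        # alt = most common non-ancestral allele among passing calls;
        # deterministic lexicographic tie-break
        from collections import Counter
        tally = Counter(a for a in passing_alleles if a != ref)
        if not tally:
            entry.update(retained=False, reasons=("no_non_ancestral_allele",))
            audit.append(entry)
            continue
        best = max(tally.values())
        alt = min(a for a, c in tally.items() if c == best)
        extra = sorted(set(tally) - {alt})
        if extra:
            entry["extra_alleles"] = tuple(extra)
        audit.append(entry)

        col = np.full(n_iso, AMBIGUOUS, dtype=np.int8)
        for j, c in enumerate(calls):
            if not c.passed:
                continue
            if c.allele == ref:
                col[j] = ANCESTRAL
            elif c.allele == alt:
                col[j] = DERIVED
            # passing third allele stays ambiguous (recorded via extra_alleles)
        geno_cols.append(col)
        snps.append(SnpRecord(snp_id=f"{rep}:{pos}", replicon_id=rep, pos=pos,
                              ref_allele=ref, alt_allele=alt,
                              mutation_class=classify_mutation_type(ref, alt)))

    calls_arr = (np.stack(geno_cols, axis=1) if geno_cols
                 else np.zeros((n_iso, 0), dtype=np.int8))
    gm = GenotypeMatrix(isolates=list(matrix.isolates), snps=snps,
                        calls=calls_arr)
    return snps, gm, audit


# ---------------------------------------------------------------------------
# mutation typing and coding effect
# ---------------------------------------------------------------------------

def classify_mutation_type(ref: str, alt: str) -> str:
    """Six-class, strand-symmetric substitution type of a ref->alt change."""
    ref, alt = ref.upper(), alt.upper()
    if ref == alt:
        raise ValueError(f"ref == alt ({ref})")
    try:
        return _CLASS_OF[(ref, alt)]
    except KeyError:
        raise ValueError(f"not a single-base substitution: {ref}>{alt}") from None


def annotate_coding_effect(snp: SnpRecord,
                           genome: ReferenceGenome) -> SnpRecord:
    """Assign gene, synonymous/nonsynonymous status and amino-acid change.

    Uses the bacterial genetic code (translation table 11).  A SNP covered by
    no annotation is intergenic.  When two genes overlap the position, the
    first in coordinate order is annotated and the conflict is warned about.
    A gene whose length is not a multiple of 3 yields an ``ambiguous`` effect.
    """
    genes = genome.genes_at(snp.replicon_id, snp.pos)
    if not genes:
        return replace(snp, gene_id=None, coding_effect="intergenic",
                       aa_change=None)
    if len(genes) > 1:
        warnings.warn(f"{snp.snp_id}: position covered by "
                      f"{[g.gene_id for g in genes]}; annotating against "
                      f"{genes[0].gene_id}")
    gene = genes[0]
    if gene.length % 3 != 0:
        warnings.warn(f"gene {gene.gene_id} length {gene.length} not a "
                      f"multiple of 3; effect ambiguous")
        return replace(snp, gene_id=gene.gene_id, coding_effect="ambiguous",
                       aa_change=None, gene_name=gene.gene_id,
                       product=gene.product)
    gene_seq = genome.gene_sequence(gene)
    if gene.strand == "+":
        offset = snp.pos - gene.start
        ref_in_gene, alt_in_gene = snp.ref_allele, snp.alt_allele
    else:
        offset = gene.end - snp.pos
        ref_in_gene = snp.ref_allele.translate(_COMPLEMENT)
        alt_in_gene = snp.alt_allele.translate(_COMPLEMENT)
    ci, within = divmod(offset, 3)
    codon = gene_seq[ci * 3: ci * 3 + 3]
    if codon[within] != ref_in_gene:
        warnings.warn(f"{snp.snp_id}: reference base mismatch in "
                      f"{gene.gene_id} (codon has {codon[within]})")
    alt_codon = codon[:within] + alt_in_gene + codon[within + 1:]
    aa_ref = str(Seq(codon).translate(table=11))
    aa_alt = str(Seq(alt_codon).translate(table=11))
    effect = "synonymous" if aa_ref == aa_alt else "nonsynonymous"
    return replace(snp, gene_id=gene.gene_id, coding_effect=effect,
                   aa_change=f"{aa_ref}{ci + 1}{aa_alt}",
                   gene_name=gene.gene_id, product=gene.product)
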