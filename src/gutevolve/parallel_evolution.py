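"""Detection of genes under parallel evolution.

A gene is flagged parallel when it carries at least two SNPs whose maximum
pairwise genomic span is within the window (default 2000 bp) and — when
genotype data are available — not all of its SNP pairs are perfectly
co-occurring (identical derived-isolate sets), since perfectly linked SNPs
are a single mutational event, not independent hits.  The SNP density per
2000 bp over the mutated span is reported as a diagnostic alongside the
primary span rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .io_formats import IsolateRecord, ReferenceGenome
from .variant_core import DERIVED, GenotypeMatrix, SnpRecord

PARALLEL, SINGLE, EXCLUDED = "parallel", "single_mutation", "excluded"


@dataclass
class GeneMutationSummary:
    gene_id: str
    snp_ids: tuple[str, ...]
    n_snps: int
    max_pairwise_span: int
    snps_per_2000bp: float
    status: str
    hosts_observed: frozenset[str] = frozenset()
    parallel_in_hosts: frozenset[str] = frozenset()
    cooccurrence_checked: bool = False
    exclusion_reason: str | None = None

    def __post_init__(self) -> None:
        if self.n_snps != len(self.snp_ids):
            raise ValueError("n_snps inconsistent with snp_ids")
        if self.status == PARALLEL and self.n_snps < 2:
            raise ValueError("parallel gene with fewer than 2 SNPs")


def _gene_status(snps: list[SnpRecord], window: int,
                 derived_sets: dict[str, frozenset[str]] | None
                 ) -> tuple[str, str | None]:
    if len(snps) == 1:
        return SINGLE, None
    span = max(s.pos for s in snps) - min(s.pos for s in snps)
    if span > window:
        return EXCLUDED, "span"
    if derived_sets is not None:
        sets = {derived_sets[s.snp_id] for s in snps}
        if len(sets) == 1:
            return EXCLUDED, "perfect_cooccurrence"
    return PARALLEL, None


def detect_parallel_genes(snps: list[SnpRecord],
                          genotypes: GenotypeMatrix | None = None,
                          genome: ReferenceGenome | None = None,
                          window: int = 2000,
                          host_of_isolate: dict[str, str] | None = None,
                          ) -> list[GeneMutationSummary]:
    """Classify every mutated gene as parallel, single_mutation or excluded.

    Intergenic SNPs are ignored.  Without a genotype matrix the co-occurrence
    exclusion cannot be evaluated and is skipped (``cooccurrence_checked`` is
    False on the output).  With host labels, the per-host scope is also
    evaluated: ``parallel_in_hosts`` lists hosts within whose own SNP set the
    rule holds.
    """
    if genome is not None:
        known = {a.gene_id for a in genome.annotations}
        for s in snps:
            if s.gene_id is not None and s.gene_id not in known:
                raise ValueError(f"{s.snp_id} references unknown gene "
                                 f"{s.gene_id!r}")

    by_gene: dict[str, list[SnpRecord]] = {}
    for s in snps:
        if s.gene_id is None:
            continue
        by_gene.setdefault(s.gene_id, []).append(s)

    derived_sets = None
    if genotypes is not None:
        derived_sets = {s.snp_id: genotypes.derived_isolates(j)
                        for j, s in enumerate(genotypes.snps)}

    host_sets: dict[str, set[str]] = {}
    if genotypes is not None and host_of_isolate:
        for j, s in enumerate(genotypes.snps):
            for iso in genotypes.derived_isolates(j):
                h = host_of_isolate.get(iso)
                if h is not None:
                    host_sets.setdefault(s.snp_id, set()).add(h)

    out = []
    for gene_id in sorted(by_gene):
        gsnps = sorted(by_gene[gene_id], key=lambda s: s.pos)
        ds = None
        if derived_sets is not None:
            ds = {s.snp_id: derived_sets.get(s.snp_id, frozenset())
                  for s in gsnps}
        status, reason = _gene_status(gsnps, window, ds)
        span = max(s.pos for s in gsnps) - min(s.pos for s in gsnps)
        density = len(gsnps) / max(span, 1) * 2000.0
        hosts_observed = frozenset(h for s in gsnps
                                   for h in host_sets.get(s.snp_id, ()))
        parallel_hosts: set[str] = set()
        if host_sets:
            for h in hosts_observed:
                sub = [s for s in gsnps if h in host_sets.get(s.snp_id, ())]
                if len(sub) >= 2:
                    st, _ = _gene_status(sub, window, ds and
                                         {s.snp_id: ds[s.snp_id] for s in sub})
                    if st == PARALLEL:
                        parallel_hosts.add(h)
        out.append(GeneMutationSummary(
            gene_id=gene_id, snp_ids=tuple(s.snp_id for s in gsnps),
            n_snps=len(gsnps), max_pairwise_span=span,
            snps_per_2000bp=density, status=status,
            hosts_observed=hosts_observed,
            parallel_in_hosts=frozenset(parallel_hosts),
            cooccurrence_checked=derived_sets is not None,
            exclusion_reason=reason))
    return out


def cross_host_consistency(genotypes: GenotypeMatrix,
                           metadata: list[IsolateRecord]) -> pd.DataFrame:
    """Gene x subject table of per-subject mutated-isolate fractions.

    Each cell is the fraction of that subject's isolates carrying at least
    one unambiguous derived allele in the gene.
    """
    by_subject: dict[str, list[int]] = {}
    meta = {r.isolate_id: r for r in metadata}
    for i, iso in enumerate(genotypes.isolates):
        rec = meta.get(iso)
        if rec is None:
            warnings.warn(f"isolate {iso} has no metadata; skipped")
            continue
        by_subject.setdefault(f"{rec.host_species}:{rec.subject_id}",
                              []).append(i)
    genes = sorted({s.gene_id for s in genotypes.snps if s.gene_id})
    rows = {}
    for subj, idx in sorted(by_subject.items()):
        if not idx:
            warnings.warn(f"subject {subj} has zero isolates; row omitted")
            continue
        row = {}
        for g in genes:
            cols = [j for j, s in enumerate(genotypes.snps) if s.gene_id == g]
            carrier = (genotypes.calls[idx][:, cols] == DERIVED).any(axis=1)
            row[g] = float(carrier.mean())
        rows[subj] = row
    return pd.DataFrame(rows).T.reindex(columns=genes)
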