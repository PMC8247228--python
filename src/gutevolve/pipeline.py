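"""End-to-end orchestration: simulate/ingest -> call SNPs -> tree, dMRCA,
spectrum -> parallel genes -> dynamics -> (mobile elements, co-evolution),
with a manifest of input/output digests for provenance.

Stochastic stages require an explicit seed; omission is an error rather than
a silent clock seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .io_formats import (PipelineConfig, read_allele_counts,
                         read_isolate_metadata, read_reference,
                         write_genotype_matrix, write_snp_table)
from .lineage_dynamics import (muller_decompose, nest_lineages,
                               snp_frequencies)
from .parallel_evolution import PARALLEL, detect_parallel_genes
from .phylogeny_spectrum import (build_nj_tree, dmrca, mutation_spectrum,
                                 pairwise_snp_distance, write_newick)
from .variant_core import annotate_coding_effect, filter_candidate_sites

INPUT_FILES = {"reference": "reference.fa", "annotations": "genes.tsv",
               "counts": "counts.tsv", "metadata": "isolates.tsv"}


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    versions: dict[str, str]
    input_digests: dict[str, str]
    output_digests: dict[str, str] = field(default_factory=dict)
    started: float = 0.0
    finished: float = 0.0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2,
                                         sort_keys=True) + "\n")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, input_dir: str | Path,
                 out_dir: str | Path) -> tuple[RunManifest, dict]:
    """Execute every applicable stage in dependency order.

    Expects ``reference.fa``, ``genes.tsv``, ``counts.tsv`` and
    ``isolates.tsv`` in ``input_dir``; writes SNP table, genotype matrix,
    newick tree, per-day dMRCA, spectrum, parallel-gene table, Muller table,
    a JSON report and the manifest into ``out_dir``.
    """
    input_dir, out_dir = Path(input_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {k: input_dir / v for k, v in INPUT_FILES.items()}
    for k, p in paths.items():
        if not p.exists():
            raise FileNotFoundError(f"missing input {k}: {p}")

    manifest = RunManifest(
        config_hash=hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest(),
        seed=config.seed,
        versions={"gutevolve": __version__},
        input_digests={k: _digest(p) for k, p in sorted(paths.items())},
        started=time.time())

    genome = read_reference(paths["reference"], paths["annotations"])
    matrix = read_allele_counts(paths["counts"])
    metadata = read_isolate_metadata(paths["metadata"])
    host_of = {r.isolate_id: r.host_species for r in metadata}

    # stage: SNP calling + annotation
    snps, genotypes, audit = filter_candidate_sites(matrix, genome, config)
    snps = [annotate_coding_effect(s, genome) for s in snps]
    genotypes.snps = snps
    write_snp_table(snps, out_dir / "snps.tsv", dialect="tsv")
    write_snp_table(snps, out_dir / "snps.vcf", dialect="vcf")
    write_genotype_matrix(genotypes, out_dir / "genotypes.tsv")
    pd.DataFrame(audit).to_csv(out_dir / "audit.tsv", sep="\t", index=False)

    report: dict = {"n_snps": len(snps),
                    "n_mutated_genes": len({s.gene_id for s in snps
                                            if s.gene_id})}

    # stage: phylogeny, dMRCA, spectrum
    if len(snps) > 0:
        dist = pairwise_snp_distance(genotypes, include_ancestor=True)
        tree = build_nj_tree(dist, root_on_ancestor=True)
        write_newick(tree, out_dir / "tree.nwk")
        days = sorted({r.day for r in metadata})
        report["dmrca_per_day"] = {
            int(d): dmrca(genotypes, [r.isolate_id for r in metadata
                                      if r.day == d])
            for d in days
            if any(r.day == d for r in metadata)}
        spectrum = mutation_spectrum(snps, "per_snp", genotypes, host_of)
        spectrum.to_csv(out_dir / "spectrum.tsv", sep="\t")
        report["spectrum_pooled"] = mutation_spectrum(snps, "per_snp") \
            .loc["pooled"].to_dict()

    # stage: parallel evolution
    summaries = detect_parallel_genes(snps, genotypes, genome,
                                      window=config.parallel_window,
                                      host_of_isolate=host_of)
    pd.DataFrame([{"gene_id": s.gene_id, "n_snps": s.n_snps,
                   "span": s.max_pairwise_span, "status": s.status,
                   "density_per_2000bp": s.snps_per_2000bp}
                  for s in summaries]).to_csv(out_dir / "parallel_genes.tsv",
                                              sep="\t", index=False)
    report["parallel_genes"] = sorted(s.gene_id for s in summaries
                                      if s.status == PARALLEL)

    # stage: lineage dynamics
    series = snp_frequencies(genotypes, metadata,
                             min_isolates=config.min_isolates)
    report["n_trajectory_snps"] = len(series)
    if series:
        tree_l = nest_lineages(genotypes, metadata,
                               nesting_tolerance=config.nesting_tolerance)
        muller = muller_decompose(tree_l)
        muller.to_csv(out_dir / "muller.tsv", sep="\t", index=False)
        report["n_lineages"] = len(tree_l.nodes) - 1  # founder excluded

    (out_dir / "report.json").write_text(json.dumps(report, indent=2,
                                                    sort_keys=True) + "\n")
    manifest.output_digests = {p.name: _digest(p)
                               for p in sorted(out_dir.glob("*"))
                               if p.name != "manifest.json" and p.is_file()}
    manifest.finished = time.time()
    manifest.to_json(out_dir / "manifest.json")
    return manifest, report
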