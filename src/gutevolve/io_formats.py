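"""Readers and writers for every external representation the pipeline touches.

External files use 1-based inclusive genomic coordinates throughout (the
convention of the confirmed-SNP table and of VCF).  Conversion to Python's
0-based half-open slices is confined to this module via
:meth:`GeneAnnotation.slice0`.

The per-site ``site_quality`` column follows the convention of the upstream
variant caller it adapts: *lower* values mean stronger variant evidence, and a
cell passes the quality filter when its quality is strictly below the
configured threshold (default 60).  Missing cells (no row in the long-format
counts table) are distinguishable from observed zero coverage so that the
isolate-failure-fraction rule can count them as failing.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """Raised when an external file violates its documented format."""


VALID_BASES = set("ACGTN")
HOST_SPECIES = ("human", "mouse", "zebrafish")
GROUPS = ("probiotic", "placebo", "invitro")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneAnnotation:
    """A protein-coding gene interval, 1-based inclusive coordinates."""

    gene_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def slice0(self) -> slice:
        """0-based half-open slice of this gene on its replicon."""
        return slice(self.start - 1, self.end)

    def contains(self, pos: int) -> bool:
        """True if the 1-based position lies inside the gene."""
        return self.start <= pos <= self.end


@dataclass
class ReferenceGenome:
    """The ancestral strain: replicon sequences plus gene annotations."""

    replicons: dict[str, str]
    annotations: list[GeneAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()
        # coordinate-sorted index for position lookups
        self._by_replicon: dict[str, list[GeneAnnotation]] = {}
        for ann in sorted(self.annotations, key=lambda a: (a.replicon_id, a.start)):
            self._by_replicon.setdefault(ann.replicon_id, []).append(ann)

    def validate(self) -> None:
        if not self.replicons:
            raise FormatError("genome has no replicons")
        for rid, seq in self.replicons.items():
            if not seq:
                raise FormatError(f"replicon {rid} has empty sequence")
            bad = set(seq.upper()) - VALID_BASES
            if bad:
                pos = next(i for i, c in enumerate(seq.upper()) if c in bad)
                raise FormatError(
                    f"replicon {rid}: non-ACGTN character {seq[pos]!r} at "
                    f"position {pos + 1}")
        seen: set[str] = set()
        for ann in self.annotations:
            if ann.gene_id in seen:
                raise FormatError(f"duplicate gene_id {ann.gene_id}")
            seen.add(ann.gene_id)
            if ann.replicon_id not in self.replicons:
                raise FormatError(
                    f"gene {ann.gene_id} references absent replicon "
                    f"{ann.replicon_id!r}")
            if ann.end > len(self.replicons[ann.replicon_id]):
                raise FormatError(
                    f"gene {ann.gene_id} extends past the end of replicon "
                    f"{ann.replicon_id}")

    def base_at(self, replicon_id: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        return self.replicons[replicon_id][pos - 1].upper()

    def genes_at(self, replicon_id: str, pos: int) -> list[GeneAnnotation]:
        """Genes covering a 1-based position, in coordinate order."""
        return [a for a in self._by_replicon.get(replicon_id, [])
                if a.contains(pos)]

    def gene_sequence(self, ann: GeneAnnotation) -> str:
        """Gene sequence in reading orientation (reverse-complemented on -)."""
        seq = self.replicons[ann.replicon_id][ann.slice0()].upper()
        if ann.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


@dataclass(frozen=True)
class IsolateRecord:
    """Metadata for one sequenced isolate of the ingested strain."""

    isolate_id: str
    host_species: str
    subject_id: str
    day: int
    group: str = "probiotic"

    def __post_init__(self) -> None:
        if self.host_species not in HOST_SPECIES:
            raise FormatError(
                f"isolate {self.isolate_id}: unknown host {self.host_species!r}")
        if self.group not in GROUPS:
            raise FormatError(
                f"isolate {self.isolate_id}: unknown group {self.group!r}")
        if self.day < 0:
            raise FormatError(f"isolate {self.isolate_id}: negative day")


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline.

    Defaults equal the study's printed values: quality < 60 passes, >=7 reads
    per strand, major-allele fraction >= 0.90, median coverage >= 10, site
    discarded when >= 1/3 of isolates fail, parallel-evolution window 2000 bp,
    SNP trajectories need >= 4 derived isolates, element presence coverage
    > 0.80 with depth > 60x, absence coverage < 0.20 or depth < 60x.
    """

    # filter cascade
    max_site_quality: float = 60.0
    site_level_quality: bool = False  # evaluate quality on the per-site median
    min_strand_depth: int = 7
    min_major_af: float = 0.90
    min_median_coverage: float = 10.0
    # discard when n_fail / n_isolates >= fail_num / fail_den (exact rational)
    fail_num: int = 1
    fail_den: int = 3
    # parallel evolution
    parallel_window: int = 2000
    # lineage dynamics
    min_isolates: int = 4
    grid_step: float = 0.5
    freq_threshold: float = 0.0
    nesting_tolerance: float = 0.10
    # mobile elements
    min_contig_length: int = 500
    id_core: float = 0.90
    evalue: float = 1e-5
    id_dedup: float = 0.90
    aln_frac: float = 0.85
    presence_min_coverage: float = 0.80
    absence_max_coverage: float = 0.20
    min_presence_depth: float = 60.0
    # community co-evolution
    fdr_q: float = 0.05
    n_permutations: int = 9999
    zero_strategy: str = "multiplicative"
    zero_delta_factor: float = 0.65
    # randomness
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# reference genome I/O
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ["gene_id", "replicon", "start", "end", "strand", "product"]


def read_reference(fasta_path: str | Path,
                   annotation_path: str | Path | None = None) -> ReferenceGenome:
    """Load a reference genome from FASTA plus a 6-column gene table."""
    replicons: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in replicons:
            raise FormatError(f"duplicate replicon id {rec.id}")
        replicons[rec.id] = str(rec.seq).upper()
    if not replicons:
        raise FormatError(f"no sequences in {fasta_path}")
    annotations: list[GeneAnnotation] = []
    if annotation_path is not None:
        annotations = read_annotations(annotation_path)
    return ReferenceGenome(replicons=replicons, annotations=annotations)


def read_annotations(path: str | Path) -> list[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"annotation table missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(GeneAnnotation(
            gene_id=row.gene_id, replicon_id=row.replicon,
            start=int(row.start), end=int(row.end), strand=row.strand,
            product="" if pd.isna(row.product) else str(row.product)))
    return out


def write_reference(genome: ReferenceGenome, fasta_path: str | Path,
                    annotation_path: str | Path | None = None) -> None:
    records = [SeqRecord(Seq(seq), id=rid, description="")
               for rid, seq in genome.replicons.items()]
    SeqIO.write(records, str(fasta_path), "fasta")
    if annotation_path is not None:
        rows = [(a.gene_id, a.replicon_id, a.start, a.end, a.strand, a.product)
                for a in genome.annotations]
        pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(
            annotation_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# allele counts I/O (long-format TSV <-> dense matrix)
# ---------------------------------------------------------------------------

COUNT_COLUMNS = ["replicon", "pos", "isolate_id",
                 "A_fwd", "A_rev", "C_fwd", "C_rev",
                 "G_fwd", "G_rev", "T_fwd", "T_rev", "site_quality"]


def read_allele_counts(tsv_path: str | Path):
    """Read a long-format stranded allele-count table into a dense matrix.

    Absent (site, isolate) rows become zero-count cells flagged missing.
    """
    from .variant_core import AlleleCountMatrix  # local import: no cycle at runtime

    df = pd.read_csv(tsv_path, sep="\t", comment="#")
    missing_cols = set(COUNT_COLUMNS) - set(df.columns)
    if missing_cols:
        raise FormatError(f"counts table missing columns {sorted(missing_cols)}")
    count_cols = COUNT_COLUMNS[3:11]
    if (df[count_cols].to_numpy() < 0).any():
        raise FormatError("negative counts in allele-count table")
    dup = df.duplicated(subset=["replicon", "pos", "isolate_id"])
    if dup.any():
        r = df[dup].iloc[0]
        raise FormatError(
            f"duplicate row for ({r['replicon']}, {r['pos']}, {r['isolate_id']})")

    sites = sorted({(str(r), int(p)) for r, p in zip(df["replicon"], df["pos"])})
    isolates = sorted(df["isolate_id"].astype(str).unique())
    site_idx = {s: i for i, s in enumerate(sites)}
    iso_idx = {s: i for i, s in enumerate(isolates)}

    counts = np.zeros((len(sites), len(isolates), 4, 2), dtype=np.int64)
    quality = np.full((len(sites), len(isolates)), np.nan)
    missing = np.ones((len(sites), len(isolates)), dtype=bool)
    base_order = "ACGT"
    for row in df.itertuples(index=False):
        i = site_idx[(str(row.replicon), int(row.pos))]
        j = iso_idx[str(row.isolate_id)]
        for b, base in enumerate(base_order):
            counts[i, j, b, 0] = getattr(row, f"{base}_fwd")
            counts[i, j, b, 1] = getattr(row, f"{base}_rev")
        quality[i, j] = row.site_quality
        missing[i, j] = False
    return AlleleCountMatrix(sites=sites, isolates=isolates, counts=counts,
                             site_quality=quality, missing=missing)


def write_allele_counts(matrix, tsv_path: str | Path) -> None:
    """Write a dense allele-count matrix back to the long-format TSV.

    Missing cells are omitted (that is what "missing" means on disk).
    """
    rows = []
    for i, (rep, pos) in enumerate(matrix.sites):
        for j, iso in enumerate(matrix.isolates):
            if matrix.missing[i, j]:
                continue
            c = matrix.counts[i, j]
            rows.append((rep, pos, iso,
                         c[0, 0], c[0, 1], c[1, 0], c[1, 1],
                         c[2, 0], c[2, 1], c[3, 0], c[3, 1],
                         matrix.site_quality[i, j]))
    with open(tsv_path, "w") as fh:
        fh.write("# stranded allele counts; site_quality: lower = stronger "
                 "variant evidence (quality < threshold passes)\n")
        pd.DataFrame(rows, columns=COUNT_COLUMNS).to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# isolate metadata I/O
# ---------------------------------------------------------------------------

def read_isolate_metadata(path: str | Path) -> list[IsolateRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    need = {"isolate_id", "host_species", "subject_id", "day", "group"}
    missing = need - set(df.columns)
    if missing:
        raise FormatError(f"metadata missing columns {sorted(missing)}")
    recs = [IsolateRecord(r.isolate_id, r.host_species, r.subject_id,
                          int(r.day), r.group)
            for r in df.itertuples(index=False)]
    if len({r.isolate_id for r in recs}) != len(recs):
        raise FormatError("duplicate isolate_id in metadata")
    return recs


def write_isolate_metadata(records: Iterable[IsolateRecord],
                           path: str | Path) -> None:
    rows = [(r.isolate_id, r.host_species, r.subject_id, r.day, r.group)
            for r in records]
    pd.DataFrame(rows, columns=["isolate_id", "host_species", "subject_id",
                                "day", "group"]).to_csv(path, sep="\t",
                                                        index=False)


# ---------------------------------------------------------------------------
# SNP table I/O (TSV and minimal VCF)
# ---------------------------------------------------------------------------

SNP_COLUMNS = ["snp_id", "replicon", "pos", "ref", "alt", "gene_id",
               "coding_effect", "aa_change", "gene_name", "product"]


def write_snp_table(snps, path: str | Path, dialect: str = "tsv") -> None:
    """Write confirmed SNP records as TSV (table-style) or minimal VCF 4.2."""
    from .variant_core import SnpRecord  # noqa: F401  (type of the elements)

    if dialect == "tsv":
        rows = []
        for s in snps:
            rows.append((s.snp_id, s.replicon_id, s.pos, s.ref_allele,
                         s.alt_allele, s.gene_id or "NA",
                         s.coding_effect or "NA", s.aa_change or "NA",
                         s.gene_name or "NA", s.product or "NA"))
        pd.DataFrame(rows, columns=SNP_COLUMNS).to_csv(path, sep="\t",
                                                       index=False)
    elif dialect == "vcf":
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##INFO=<ID=GENE,Number=1,Type=String,'
                     'Description="Gene id or NA">\n')
            fh.write('##INFO=<ID=MT,Number=1,Type=String,'
                     'Description="Coding effect">\n')
            fh.write('##INFO=<ID=AAC,Number=1,Type=String,'
                     'Description="Amino acid change">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for s in snps:
                info = (f"GENE={s.gene_id or 'NA'};MT={s.coding_effect or 'NA'};"
                        f"AAC={s.aa_change or 'NA'}")
                fh.write(f"{s.replicon_id}\t{s.pos}\t{s.snp_id}\t{s.ref_allele}"
                         f"\t{s.alt_allele}\t.\tPASS\t{info}\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_snp_table(path: str | Path):
    """Read a TSV SNP table written by :func:`write_snp_table`."""
    from .variant_core import SnpRecord, classify_mutation_type

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(SNP_COLUMNS[:8]) - set(df.columns)
    if missing:
        raise FormatError(f"SNP table missing columns {sorted(missing)}")
    out = []
    for r in df.itertuples(index=False):
        def _na(v):
            return None if (pd.isna(v) or v == "NA") else v
        out.append(SnpRecord(
            snp_id=r.snp_id, replicon_id=r.replicon, pos=int(r.pos),
            ref_allele=r.ref, alt_allele=r.alt, gene_id=_na(r.gene_id),
            mutation_class=classify_mutation_type(r.ref, r.alt),
            coding_effect=_na(r.coding_effect), aa_change=_na(r.aa_change),
            gene_name=_na(getattr(r, "gene_name", None)),
            product=_na(getattr(r, "product", None))))
    return out


def load_confirmed_snps():
    """The bundled 22 PCR-confirmed SNPs of the probiotic strain."""
    with resources.as_file(resources.files("gutevolve.data")
                           .joinpath("table1_snps.tsv")) as p:
        return read_snp_table(p)


# ---------------------------------------------------------------------------
# genotype matrix I/O
# ---------------------------------------------------------------------------

def write_genotype_matrix(gm, path: str | Path) -> None:
    """Isolates x SNPs call table: 0 ancestral, 1 derived, . ambiguous."""
    sym = {0: "0", 1: "1", -1: "."}
    with open(path, "w") as fh:
        fh.write("isolate_id\t" + "\t".join(s.snp_id for s in gm.snps) + "\n")
        for i, iso in enumerate(gm.isolates):
            fh.write(iso + "\t" +
                     "\t".join(sym[int(v)] for v in gm.calls[i]) + "\n")


def read_genotype_matrix(path: str | Path, snps):
    """Read back a genotype matrix; ``snps`` supplies the column records."""
    from .variant_core import GenotypeMatrix

    df = pd.read_csv(path, sep="\t", dtype=str).set_index("isolate_id")
    by_id = {s.snp_id: s for s in snps}
    missing = set(df.columns) - set(by_id)
    if missing:
        raise FormatError(f"genotype columns without SNP records: {sorted(missing)}")
    recs = [by_id[c] for c in df.columns]
    sym = {"0": 0, "1": 1, ".": -1}
    calls = np.array([[sym[v] for v in row] for row in df.to_numpy()],
                     dtype=np.int8)
    return GenotypeMatrix(isolates=list(df.index), snps=recs, calls=calls)
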