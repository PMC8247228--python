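"""Forward-time generator of every input the pipeline consumes, with ground
truth for parameter-recovery testing.

The generator emulates the study system: a clonal probiotic founder ingested
by several host subjects, adapting over a 28-day window by acquiring nested
selected mutations, sampled as whole-genome-sequenced isolates on days 3, 7,
14, 21 and 28; plus a resident gut community in which the probiotic's
competitor species accumulate SNPs at strongly elevated rates.

Lineage frequencies evolve by discrete-generation Wright-Fisher resampling
with selection (expected frequency proportional to current frequency times
1 + s, renormalised).  The default scenario plants a scripted birth schedule
of five nested branches carrying 22 SNPs over 12 genes (five genes with
multiple SNPs, three intergenic SNPs), echoing the structure of the
confirmed-SNP table; each multi-SNP gene places its SNPs on different
branches so the hits are genuinely independent.  In stochastic mode
(``mutation_rate`` > 0 and no plan) each birth adds exactly one SNP.

Everything is reproducible bit-for-bit from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .io_formats import GeneAnnotation, IsolateRecord, ReferenceGenome
from .variant_core import (AlleleCountMatrix, GenotypeMatrix, SnpRecord,
                           ANCESTRAL, DERIVED,
                           annotate_coding_effect, classify_mutation_type)

FOUNDER = "founder"
BASES = "ACGT"


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LineageSpec:
    """One scripted sublineage birth: day, parent, fitness, SNP slots.

    ``fitness_advantage`` is the lineage's absolute selection coefficient
    relative to the founder (per generation).  ``snp_slots`` name the gene
    each new SNP lands in (a plan gene key, or ``None`` for intergenic).
    """

    name: str
    parent: Optional[str]
    birth_day: int
    fitness_advantage: float
    snp_slots: tuple[Optional[str], ...]


def default_lineage_plan() -> tuple[LineageSpec, ...]:
    """Five nested branches, 22 SNPs over 12 genes (5 multi-SNP) + 3 intergenic."""
    return (
        LineageSpec("E1", None, 1, 0.30, ("gA", "g6", None)),
        LineageSpec("E1-A", "E1", 3, 0.38,
                    ("gB", "gC", "gD", "g7", "g8", None)),
        LineageSpec("E1-B", "E1", 3, 0.42, ("gA", "gD", "g9", "g10")),
        LineageSpec("E1-B-1", "E1-B", 7, 0.50,
                    ("gB", "gD", "gE", "g11", None)),
        LineageSpec("E1-B-2", "E1-B", 9, 0.48, ("gC", "gD", "gE", "g12")),
    )


@dataclass
class SimConfig:
    """All knobs of the generator; defaults are the study-scale scenario."""

    # genome layout: one chromosome + four plasmids
    chromosome_length: int = 120_000
    plasmid_lengths: tuple[int, ...] = (9_000, 8_000, 7_000, 6_000)
    n_genes: int = 80
    gene_length: int = 900           # bp, multiple of 3
    gene_spacing: int = 300
    # hosts and sampling
    hosts: dict[str, int] = field(
        default_factory=lambda: {"human": 3, "mouse": 2})
    days: tuple[int, ...] = (3, 7, 14, 21, 28)
    isolates_per_day: int = 20       # per (subject, day)
    # evolution
    pop_size: int = 2_000
    generations_per_day: int = 2
    birth_frequency: float = 0.08
    lineage_plan: tuple[LineageSpec, ...] = field(
        default_factory=default_lineage_plan)
    mutation_rate: float = 0.0       # per-lineage per-day extra birth prob
    # sequencing
    mean_depth: float = 60.0
    depth_shape: float = 20.0        # negative-binomial overdispersion
    error_rate: float = 0.005
    strand_prob: float = 0.5
    missing_prob: float = 0.02
    n_background_sites: int = 40     # monomorphic sites exercising rejection
    # mobile elements: one carried by everything, one gained by a branch
    element_lengths: tuple[int, ...] = (1_600, 1_200)
    element_carriers: tuple[str, ...] = ("*", "E1-B")
    n_core_contigs: int = 2
    core_contig_length: int = 2_000
    # resident community
    n_species: int = 24
    n_competitors: int = 8
    community_subjects_per_group: int = 5
    community_days: tuple[int, ...] = (0, 7, 14, 21, 28)
    competitor_snp_rate: float = 2.5         # SNPs/day in the probiotic group
    noncompetitor_snp_rate: float = 0.07
    placebo_snp_rate: float = 0.065
    probiotic_self_snp_rate: float = 0.36
    abundance_coupling: float = 0.8          # competitor vs probiotic (log scale)
    abundance_noise_sd: float = 0.3
    seed: int = 1

    def __post_init__(self) -> None:
        if not all(0 <= p <= 1 for p in (self.birth_frequency,
                                         self.error_rate, self.strand_prob,
                                         self.missing_prob,
                                         self.mutation_rate)):
            raise ValueError("probabilities must lie in [0, 1]")
        if list(self.days) != sorted(set(self.days)):
            raise ValueError("sampling schedule must be strictly increasing")
        if self.gene_length % 3:
            raise ValueError("gene_length must be a multiple of 3")


# ---------------------------------------------------------------------------
# truth containers
# ---------------------------------------------------------------------------

@dataclass
class TrueLineage:
    name: str
    parent: Optional[str]
    own_snp_ids: frozenset[str]
    all_snp_ids: frozenset[str]      # own plus every ancestor's
    fitness_advantage: float
    birth_day: int


@dataclass
class SimulationTruth:
    genome: ReferenceGenome
    snps: list[SnpRecord]
    lineages: dict[str, TrueLineage]
    # (host, subject) -> DataFrame indexed by day, columns = lineage names,
    # values = exclusive occupancy frequencies (rows sum to 1)
    occupancy: dict[tuple[str, str], pd.DataFrame]
    background_sites: list[tuple[str, int]]
    elements: list[tuple[str, str, frozenset[str]]]  # (id, sequence, carriers)
    config: SimConfig

    def raw_frequency(self, host: str, subject: str) -> pd.DataFrame:
        """Cumulative (lineage + descendants) frequencies per day."""
        occ = self.occupancy[(host, subject)]
        out = occ.copy()
        for name in self._postorder():
            lin = self.lineages[name]
            kids = [k for k, v in self.lineages.items() if v.parent == name]
            out[name] = occ[name] + sum(out[k] for k in kids)
        out[FOUNDER] = 1.0
        return out

    def _postorder(self) -> list[str]:
        order, seen = [], set()

        def walk(n: str) -> None:
            for k, v in self.lineages.items():
                if v.parent == n:
                    walk(k)
            if n not in seen:
                order.append(n)
                seen.add(n)
        roots = [n for n, v in self.lineages.items() if v.parent is None]
        for r in roots:
            walk(r)
        return [n for n in order if n != FOUNDER]

    def topology(self) -> set[tuple[frozenset, Optional[frozenset]]]:
        """Same order-free encoding as the recovered lineage tree."""
        out = set()
        for lin in self.lineages.values():
            if lin.name == FOUNDER:
                continue
            parent = self.lineages.get(lin.parent) if lin.parent else None
            out.add((lin.all_snp_ids,
                     parent.all_snp_ids if parent and parent.name != FOUNDER
                     else None))
        return out

    def multi_snp_genes(self) -> set[str]:
        by_gene: dict[str, int] = {}
        for s in self.snps:
            if s.gene_id:
                by_gene[s.gene_id] = by_gene.get(s.gene_id, 0) + 1
        return {g for g, n in by_gene.items() if n >= 2}


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def _build_genome(cfg: SimConfig, rng: np.random.Generator) -> ReferenceGenome:
    replicons = {"chromosome": _random_sequence(rng, cfg.chromosome_length)}
    for i, ln in enumerate(cfg.plasmid_lengths):
        replicons[f"plasmid{i + 1}"] = _random_sequence(rng, ln)
    pitch = cfg.gene_length + cfg.gene_spacing
    if 100 + cfg.n_genes * pitch > cfg.chromosome_length:
        raise ValueError("chromosome too short for the requested gene count")
    annotations = []
    for i in range(cfg.n_genes):
        start = 101 + i * pitch
        annotations.append(GeneAnnotation(
            gene_id=f"gene{i:04d}", replicon_id="chromosome",
            start=start, end=start + cfg.gene_length - 1,
            strand="+" if i % 2 == 0 else "-",
            product="hypothetical protein"))
    return ReferenceGenome(replicons=replicons, annotations=annotations)


# plan gene keys -> deterministic gene indices (well separated on the genome)
_PLAN_GENE_INDEX = {"gA": 5, "gB": 12, "gC": 19, "gD": 26, "gE": 33,
                    "g6": 40, "g7": 44, "g8": 48, "g9": 52, "g10": 56,
                    "g11": 60, "g12": 64}


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------

def simulate_evolution(config: SimConfig | None = None,
                       seed: int | None = None) -> SimulationTruth:
    """Run the forward-time lineage simulation for every host subject."""
    cfg = config or SimConfig()
    root_seed = cfg.seed if seed is None else seed
    ss = np.random.SeedSequence(root_seed)
    s_genome, s_snps, s_subjects, s_elements = ss.spawn(4)
    rng = np.random.default_rng(s_genome)
    genome = _build_genome(cfg, rng)

    # --- plant SNPs according to the lineage plan -------------------------
    snp_rng = np.random.default_rng(s_snps)
    lineages: dict[str, TrueLineage] = {
        FOUNDER: TrueLineage(FOUNDER, None, frozenset(), frozenset(), 0.0, 0)}
    snps: list[SnpRecord] = []
    used_positions: set[int] = set()
    counter = 0
    gene_list = genome.annotations

    def plant(gene_key: Optional[str]) -> SnpRecord:
        nonlocal counter
        counter += 1
        if gene_key is None:
            # intergenic: inside a gap between genes
            while True:
                gap = int(snp_rng.integers(0, cfg.n_genes))
                ann = gene_list[gap]
                pos = ann.end + 1 + int(snp_rng.integers(10, cfg.gene_spacing - 10))
                if pos not in used_positions and pos <= cfg.chromosome_length:
                    break
        else:
            ann = gene_list[_PLAN_GENE_INDEX[gene_key]]
            while True:
                pos = ann.start + int(snp_rng.integers(0, ann.length))
                if pos not in used_positions:
                    break
        used_positions.add(pos)
        ref = genome.base_at("chromosome", pos)
        alt = str(snp_rng.choice([b for b in BASES if b != ref]))
        rec = SnpRecord(snp_id=f"S{counter:02d}", replicon_id="chromosome",
                        pos=pos, ref_allele=ref, alt_allele=alt,
                        mutation_class=classify_mutation_type(ref, alt))
        return annotate_coding_effect(rec, genome)

    for spec in cfg.lineage_plan:
        own = frozenset()
        new = [plant(k) for k in spec.snp_slots]
        snps.extend(new)
        own = frozenset(s.snp_id for s in new)
        parent = spec.parent or FOUNDER
        lineages[spec.name] = TrueLineage(
            name=spec.name, parent=parent, own_snp_ids=own,
            all_snp_ids=own | lineages[parent].all_snp_ids,
            fitness_advantage=spec.fitness_advantage,
            birth_day=spec.birth_day)

    # --- Wright-Fisher occupancy per subject ------------------------------
    max_day = max(max(cfg.days),
                  max((l.birth_day for l in lineages.values()), default=0))
    names = [FOUNDER] + [s.name for s in cfg.lineage_plan]
    fitness = np.array([1.0 + lineages[n].fitness_advantage for n in names])
    births_on = {}
    for spec in cfg.lineage_plan:
        births_on.setdefault(spec.birth_day, []).append(spec)

    occupancy: dict[tuple[str, str], pd.DataFrame] = {}
    subject_seeds = s_subjects.spawn(sum(cfg.hosts.values()))
    k = 0
    for host, n_subjects in cfg.hosts.items():
        for si in range(1, n_subjects + 1):
            subj = f"{host}{si}"
            srng = np.random.default_rng(subject_seeds[k]); k += 1
            freq = np.zeros(len(names)); freq[0] = 1.0
            rows = {0: freq.copy()}
            for day in range(1, max_day + 1):
                for spec in births_on.get(day, []):
                    pi = names.index(spec.parent or FOUNDER)
                    ci = names.index(spec.name)
                    take = min(cfg.birth_frequency, freq[pi] / 2)
                    freq[pi] -= take
                    freq[ci] += take
                for _ in range(cfg.generations_per_day):
                    p = freq * fitness
                    total = p.sum()
                    if total <= 0:
                        break
                    p /= total
                    freq = srng.multinomial(cfg.pop_size, p) / cfg.pop_size
                rows[day] = freq.copy()
            occupancy[(host, subj)] = pd.DataFrame.from_dict(
                rows, orient="index", columns=names).sort_index()

    # --- mobile elements --------------------------------------------------
    ername = np.random.default_rng(s_elements)
    elements = []
    for i, (ln, carrier) in enumerate(zip(cfg.element_lengths,
                                          cfg.element_carriers)):
        seq = _random_sequence(ername, ln)
        if carrier == "*":
            carriers = frozenset(names)
        else:
            carriers = frozenset(
                [carrier] + [n for n in names
                             if _descends(lineages, n, carrier)])
        elements.append((f"ME{i + 1:03d}", seq, carriers))

    # --- background (monomorphic) candidate sites -------------------------
    bg_rng = np.random.default_rng(np.random.SeedSequence(root_seed + 10_007))
    background = []
    while len(background) < cfg.n_background_sites:
        pos = int(bg_rng.integers(1, cfg.chromosome_length + 1))
        if pos not in used_positions:
            used_positions.add(pos)
            background.append(("chromosome", pos))
    background.sort()

    return SimulationTruth(genome=genome, snps=snps, lineages=lineages,
                           occupancy=occupancy, background_sites=background,
                           elements=elements, config=cfg)


def _descends(lineages: dict[str, TrueLineage], name: str,
              ancestor: str) -> bool:
    cur = lineages[name].parent
    while cur is not None:
        if cur == ancestor:
            return True
        cur = lineages[cur].parent
    return False


# ---------------------------------------------------------------------------
# isolate sampling and read-count emission
# ---------------------------------------------------------------------------

@dataclass
class SampledData:
    records: list[IsolateRecord]
    counts: AlleleCountMatrix
    contigs: dict[str, list[str]]
    element_coverage: dict[tuple[str, str], tuple[float, float]]
    true_genotypes: GenotypeMatrix
    isolate_lineage: dict[str, str]


def sample_isolates_and_reads(truth: SimulationTruth,
                              config: SimConfig | None = None,
                              seed: int | None = None) -> SampledData:
    """Draw isolates from lineage occupancies and emit stranded read counts.

    Isolates are multinomial draws from each (subject, day) occupancy; per
    candidate site and isolate, total depth is negative-binomial around the
    configured mean, reads split between strands binomially, and bases err
    uniformly at the configured rate.  Mobile-element carriage becomes
    accessory contigs plus per-element coverage/depth evidence.
    """
    cfg = config or truth.config
    root_seed = (cfg.seed + 1_000_003) if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence(root_seed))

    names = list(truth.occupancy[next(iter(truth.occupancy))].columns)
    records: list[IsolateRecord] = []
    isolate_lineage: dict[str, str] = {}
    for (host, subj), occ in sorted(truth.occupancy.items()):
        for day in cfg.days:
            draws = rng.multinomial(cfg.isolates_per_day,
                                    occ.loc[day].to_numpy())
            k = 0
            for li, n in enumerate(draws):
                for _ in range(n):
                    k += 1
                    iso = f"{subj}.d{day:02d}.i{k:02d}"
                    records.append(IsolateRecord(iso, host, subj, day))
                    isolate_lineage[iso] = names[li]

    sites = sorted([(s.replicon_id, s.pos) for s in truth.snps]
                   + truth.background_sites)
    site_snp = {(s.replicon_id, s.pos): s for s in truth.snps}
    isolates = [r.isolate_id for r in records]
    n_s, n_i = len(sites), len(isolates)
    counts = np.zeros((n_s, n_i, 4, 2), dtype=np.int64)
    quality = np.full((n_s, n_i), np.nan)
    missing = np.ones((n_s, n_i), dtype=bool)
    base_idx = {b: i for i, b in enumerate(BASES)}

    # depth ~ NegBin(mean, shape); strand split Binomial(strand_prob)
    p_nb = cfg.depth_shape / (cfg.depth_shape + cfg.mean_depth)
    for j, rec in enumerate(records):
        lin = truth.lineages[isolate_lineage[rec.isolate_id]]
        for i, site in enumerate(sites):
            if rng.random() < cfg.missing_prob:
                continue
            snp = site_snp.get(site)
            true_base = (snp.alt_allele if snp and snp.snp_id in lin.all_snp_ids
                         else truth.genome.base_at(*site))
            depth = int(rng.negative_binomial(cfg.depth_shape, p_nb))
            if depth == 0:
                continue
            n_err = rng.binomial(depth, cfg.error_rate)
            others = [b for b in BASES if b != true_base]
            err_counts = rng.multinomial(n_err, [1 / 3] * 3)
            per_base = np.zeros(4, dtype=np.int64)
            per_base[base_idx[true_base]] = depth - n_err
            for b, c in zip(others, err_counts):
                per_base[base_idx[b]] += c
            fwd = rng.binomial(per_base, cfg.strand_prob)
            counts[i, j, :, 0] = fwd
            counts[i, j, :, 1] = per_base - fwd
            quality[i, j] = rng.uniform(5.0, 30.0)
            missing[i, j] = False

    acm = AlleleCountMatrix(sites=sites, isolates=isolates, counts=counts,
                            site_quality=quality, missing=missing)

    # true genotype matrix for recovery scoring
    calls = np.zeros((n_i, len(truth.snps)), dtype=np.int8)
    for j, rec in enumerate(records):
        lin = truth.lineages[isolate_lineage[rec.isolate_id]]
        for m, s in enumerate(truth.snps):
            calls[j, m] = DERIVED if s.snp_id in lin.all_snp_ids else ANCESTRAL
    gm = GenotypeMatrix(isolates=isolates, snps=list(truth.snps), calls=calls)

    # contigs: shared core substrings + carried accessory elements
    chrom = truth.genome.replicons["chromosome"]
    core = [chrom[5_000 + t * 20_000: 5_000 + t * 20_000
                  + cfg.core_contig_length]
            for t in range(cfg.n_core_contigs)]
    contigs: dict[str, list[str]] = {}
    element_cov: dict[tuple[str, str], tuple[float, float]] = {}
    for rec in records:
        lin_name = isolate_lineage[rec.isolate_id]
        mine = list(core)
        for eid, seq, carriers in truth.elements:
            carried = lin_name in carriers
            if carried:
                mine.append(seq)
                cov = float(rng.uniform(0.90, 1.0))
                depth = float(rng.uniform(65.0, 90.0))
            else:
                cov = float(rng.uniform(0.0, 0.10))
                depth = float(rng.uniform(0.0, 10.0))
            element_cov[(eid, rec.isolate_id)] = (cov, depth)
        contigs[rec.isolate_id] = mine

    return SampledData(records=records, counts=acm, contigs=contigs,
                       element_coverage=element_cov, true_genotypes=gm,
                       isolate_lineage=isolate_lineage)


# ---------------------------------------------------------------------------
# resident community
# ---------------------------------------------------------------------------

@dataclass
class CommunitySim:
    abundance: pd.DataFrame          # samples x species, rows sum to 1
    sample_metadata: pd.DataFrame    # sample_id -> group, subject, day
    snp_profiles: pd.DataFrame       # long: species, subject, group, day, count
    true_labels: dict[str, str]
    probiotic_id: str = "probiotic"


def simulate_community(config: SimConfig | None = None,
                       seed: int | None = None) -> CommunitySim:
    """Log-normal community with competitor species negatively coupled to the
    probiotic, and class-specific Poisson SNP accumulation."""
    cfg = config or SimConfig()
    root_seed = (cfg.seed + 2_000_003) if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence(root_seed))

    competitors = [f"comp{i:02d}" for i in range(1, cfg.n_competitors + 1)]
    others = [f"res{i:02d}" for i in range(1,
                                           cfg.n_species - cfg.n_competitors)]
    species = ["probiotic"] + competitors + others
    base = {sp: rng.normal(0.0, 1.2) for sp in species}

    rows_ab, rows_meta = [], []
    for group in ("probiotic", "placebo"):
        for si in range(1, cfg.community_subjects_per_group + 1):
            subj = f"{group[:4]}{si}"
            for day in cfg.community_days:
                if group == "probiotic":
                    p_log = 1.5 - 0.06 * day + rng.normal(0, cfg.abundance_noise_sd)
                else:
                    p_log = -6.0 + rng.normal(0, 0.2)
                logs = {"probiotic": p_log}
                for sp in competitors:
                    logs[sp] = (base[sp] - cfg.abundance_coupling * p_log
                                + rng.normal(0, cfg.abundance_noise_sd))
                for sp in others:
                    logs[sp] = base[sp] + rng.normal(0, cfg.abundance_noise_sd)
                vec = np.exp(np.array([logs[sp] for sp in species]))
                vec /= vec.sum()
                sid = f"{subj}.d{day:02d}"
                rows_ab.append(pd.Series(vec, index=species, name=sid))
                rows_meta.append((sid, group, subj, day))
    abundance = pd.DataFrame(rows_ab)
    meta = pd.DataFrame(rows_meta, columns=["sample_id", "group",
                                            "subject_id", "day"]
                        ).set_index("sample_id")

    rates = {}
    for sp in species:
        if sp == "probiotic":
            rates[sp] = cfg.probiotic_self_snp_rate
        elif sp in competitors:
            rates[sp] = cfg.competitor_snp_rate
        else:
            rates[sp] = cfg.noncompetitor_snp_rate
    prof_rows = []
    for group in ("probiotic", "placebo"):
        for si in range(1, cfg.community_subjects_per_group + 1):
            subj = f"{group[:4]}{si}"
            for sp in species:
                rate = rates[sp] if group == "probiotic" else cfg.placebo_snp_rate
                count, prev = 0, 0
                for day in sorted(set(cfg.community_days) | {0}):
                    if day > 0:
                        count += int(rng.poisson(rate * (day - prev)))
                    prev = day
                    prof_rows.append((sp, subj, group, day, count))
    profiles = pd.DataFrame(prof_rows, columns=["species_id", "subject_id",
                                                "group", "day", "snp_count"])

    labels = {sp: ("probiotic_self" if sp == "probiotic"
                   else "competitor" if sp in competitors
                   else "non_competitor") for sp in species}
    return CommunitySim(abundance=abundance, sample_metadata=meta,
                        snp_profiles=profiles, true_labels=labels)
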