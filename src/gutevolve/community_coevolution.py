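"""Resident-microbiome evolutionary-response statistics.

Relative-abundance tables are centred log-ratio (CLR) transformed (with
multiplicative zero replacement) before correlation work; species whose CLR
abundance is significantly negatively associated with the probiotic across
samples are labelled its competitors.  Per-species SNP counts, referenced to
each subject's day-0 baseline, are then contrasted between competitors and
non-competitors with a Wilcoxon rank-sum test, and each subject's
evolutionary displacement from baseline is summarised as the Euclidean norm
of its per-species SNP-count vector.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

COMPETITOR = "competitor"
NON_COMPETITOR = "non_competitor"
POSITIVE_ASSOCIATE = "positive_associate"
PROBIOTIC_SELF = "probiotic_self"


@dataclass(frozen=True)
class SpeciesSnpProfile:
    """SNP counts of one resident species in one subject vs day-0 baseline."""

    species_id: str
    subject_id: str
    group: str
    counts: tuple[tuple[int, float], ...]  # (day, snp_count) pairs

    def __post_init__(self) -> None:
        for day, c in self.counts:
            if c < 0:
                raise ValueError(f"{self.species_id}: negative SNP count")
            if day == 0 and c != 0:
                raise ValueError(f"{self.species_id}: day-0 count must be 0")


def profiles_to_frame(profiles: list[SpeciesSnpProfile]) -> pd.DataFrame:
    rows = [(p.species_id, p.subject_id, p.group, day, c)
            for p in profiles for day, c in p.counts]
    return pd.DataFrame(rows, columns=["species_id", "subject_id", "group",
                                       "day", "snp_count"])


# ---------------------------------------------------------------------------
# CLR transform
# ---------------------------------------------------------------------------

def clr_transform(table: pd.DataFrame, zero_strategy: str = "multiplicative",
                  delta_factor: float = 0.65) -> pd.DataFrame:
    """Centred log-ratio transform of a samples x species abundance table.

    Rows must be compositions (sum 1 within 1e-6).  Zeros are replaced by
    ``multiplicative`` replacement (delta = ``delta_factor`` x the row's
    minimum nonzero value, non-zeros rescaled to preserve the unit sum) or a
    uniform ``pseudocount``.  Each transformed row sums to zero.
    """
    x = table.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("negative abundances")
    row_sums = x.sum(axis=1)
    zero_rows = np.where(row_sums == 0)[0]
    if zero_rows.size:
        raise ValueError(f"all-zero sample {table.index[zero_rows[0]]!r}")
    if not np.allclose(row_sums, 1.0, atol=1e-6):
        bad = table.index[np.argmax(np.abs(row_sums - 1.0))]
        raise ValueError(f"rows must sum to 1 (sample {bad!r} sums to "
                         f"{row_sums[np.argmax(np.abs(row_sums - 1.0))]:.4f})")
    out = x.copy()
    if zero_strategy == "multiplicative":
        for i in range(out.shape[0]):
            row = out[i]
            zeros = row == 0
            if zeros.any():
                delta = delta_factor * row[~zeros].min()
                row[~zeros] *= 1.0 - zeros.sum() * delta
                row[zeros] = delta
    elif zero_strategy == "pseudocount":
        nz = out[out > 0]
        pseudo = delta_factor * nz.min()
        out = out + pseudo
        out /= out.sum(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown zero_strategy {zero_strategy!r}")
    logx = np.log(out)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=table.index, columns=table.columns)


# ---------------------------------------------------------------------------
# co-occurrence network (rank correlation + permutation FDR)
# ---------------------------------------------------------------------------

def cooccurrence_network(clr_table: pd.DataFrame, probiotic_id: str,
                         fdr_q: float = 0.05, n_permutations: int = 999,
                         seed: int | None = None
                         ) -> tuple[pd.DataFrame, dict[str, str]]:
    """Signed species-species edges and competitor labels.

    Spearman correlations on the CLR table; per-pair permutation p-values
    (independent column shuffles) are FDR-thresholded at ``fdr_q``
    (Benjamini-Hochberg).  A species with a significant negative edge to the
    probiotic is a competitor; a significant positive edge marks a positive
    associate; others are non-competitors.  The probiotic itself is labelled
    exactly once as ``probiotic_self``.
    """
    if probiotic_id not in clr_table.columns:
        raise ValueError(f"{probiotic_id!r} not in table")
    if clr_table.shape[0] < 8:
        raise ValueError("need at least 8 samples")
    variances = clr_table.var(axis=0)
    dropped = list(variances.index[variances == 0])
    if dropped:
        warnings.warn(f"zero-variance species excluded: {dropped}")
    table = clr_table.drop(columns=dropped)
    species = list(table.columns)
    n_samp = len(table)
    ranks = np.apply_along_axis(stats.rankdata, 0, table.to_numpy())
    obs = np.corrcoef(ranks, rowvar=False)

    rng = np.random.default_rng(seed)
    n_sp = len(species)
    exceed = np.zeros((n_sp, n_sp))
    for _ in range(n_permutations):
        perm = np.empty_like(ranks)
        for k in range(n_sp):
            perm[:, k] = ranks[rng.permutation(n_samp), k]
        null = np.corrcoef(perm, rowvar=False)
        exceed += np.abs(null) >= np.abs(obs)
    pvals = (exceed + 1.0) / (n_permutations + 1.0)

    pairs = list(itertools.combinations(range(n_sp), 2))
    flat_p = np.array([pvals[i, j] for i, j in pairs])
    reject, q, *_ = multipletests(flat_p, alpha=fdr_q, method="fdr_bh")

    rows = []
    for (i, j), rej, qv, pv in zip(pairs, reject, q, flat_p):
        rows.append((species[i], species[j], float(obs[i, j]),
                     float(pv), float(qv), bool(rej)))
    edges = pd.DataFrame(rows, columns=["species_a", "species_b", "rho",
                                        "p_value", "q_value", "significant"])

    labels = {}
    for sp in clr_table.columns:
        if sp == probiotic_id:
            labels[sp] = PROBIOTIC_SELF
            continue
        hit = edges[(edges["significant"])
                    & (((edges["species_a"] == sp)
                        & (edges["species_b"] == probiotic_id))
                       | ((edges["species_b"] == sp)
                          & (edges["species_a"] == probiotic_id)))]
        if len(hit) and (hit["rho"] < 0).any():
            labels[sp] = COMPETITOR
        elif len(hit):
            labels[sp] = POSITIVE_ASSOCIATE
        else:
            labels[sp] = NON_COMPETITOR
    return edges, labels


# ---------------------------------------------------------------------------
# SNP accumulation statistics
# ---------------------------------------------------------------------------

@dataclass
class AccumulationStats:
    group_means: pd.DataFrame        # (group, day) -> mean SNPs per species
    euclidean: pd.DataFrame          # (group, subject, day) -> distance from day 0
    rates: pd.DataFrame              # (group, day) -> mean SNPs per elapsed day
    wilcoxon_stat: float | None
    wilcoxon_p: float | None
    notes: list[str] = field(default_factory=list)


def snp_accumulation_stats(profiles: pd.DataFrame | list[SpeciesSnpProfile],
                           labels: dict[str, str] | None = None
                           ) -> AccumulationStats:
    """Summaries and the competitor vs non-competitor contrast.

    ``profiles`` is the long table (species_id, subject_id, group, day,
    snp_count).  The Wilcoxon rank-sum contrast compares final-day counts of
    competitor vs non-competitor species in the probiotic group; with an
    empty class the test is skipped with a notice.
    """
    if not isinstance(profiles, pd.DataFrame):
        profiles = profiles_to_frame(profiles)
    df = profiles.sort_values(["group", "subject_id", "species_id", "day"])
    if (df["snp_count"] < 0).any():
        raise ValueError("negative SNP counts")
    notes: list[str] = []

    group_means = (df.groupby(["group", "day"])["snp_count"].mean()
                   .rename("mean_snps").reset_index())

    rows = []
    for (group, subj, day), grp in df.groupby(["group", "subject_id", "day"]):
        vec = grp.set_index("species_id")["snp_count"]
        rows.append((group, subj, day, float(np.linalg.norm(vec.to_numpy()))))
    euclidean = pd.DataFrame(rows, columns=["group", "subject_id", "day",
                                            "euclidean_from_day0"])

    rates = group_means.copy()
    rates["snps_per_day"] = np.where(rates["day"] > 0,
                                     rates["mean_snps"] / rates["day"], 0.0)

    stat = p = None
    if labels:
        final_day = df["day"].max()
        probiotic = df[(df["group"] == "probiotic") & (df["day"] == final_day)]
        comp = probiotic[probiotic["species_id"].map(labels) == COMPETITOR]
        nonc = probiotic[probiotic["species_id"].map(labels) == NON_COMPETITOR]
        if len(comp) == 0 or len(nonc) == 0:
            notes.append("competitor/non-competitor contrast skipped: "
                         "empty class")
        else:
            res = stats.mannwhitneyu(comp["snp_count"], nonc["snp_count"],
                                     alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
    else:
        notes.append("no labels supplied; contrast not computed")
    return AccumulationStats(group_means=group_means, euclidean=euclidean,
                             rates=rates, wilcoxon_stat=stat, wilcoxon_p=p,
                             notes=notes)
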