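"""SNP distance matrices, neighbor-joining trees rooted on the ancestral
strain, the dMRCA statistic, and the six-class mutation spectrum.

Pairwise distances only count positions at which *both* isolates carry an
unambiguous call, mirroring the calling cascade's treatment of ambiguity.
dMRCA for a set of isolates restricts to SNP positions polymorphic within
that set, counts derived alleles per isolate there, and averages.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio
from skbio.tree import TreeNode, nj

from .variant_core import (AMBIGUOUS, ANCESTRAL, DERIVED, MUTATION_CLASSES,
                           GenotypeMatrix, SnpRecord)

ANCESTOR_ID = "ancestor"


@dataclass
class DistanceMatrix:
    """Symmetric SNP distances with the per-pair comparable-position count."""

    ids: list[str]
    distances: np.ndarray        # float, NaN where undefined
    comparable: np.ndarray       # int, positions unambiguous in both isolates

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.distances.shape != (n, n) or self.comparable.shape != (n, n):
            raise ValueError("matrix shape inconsistent with ids")
        if not np.allclose(np.nan_to_num(self.distances),
                           np.nan_to_num(self.distances.T)):
            raise ValueError("distance matrix not symmetric")

    def has_undefined(self) -> bool:
        off = ~np.eye(len(self.ids), dtype=bool)
        return bool(np.isnan(self.distances[off]).any())


def pairwise_snp_distance(genotypes: GenotypeMatrix,
                          include_ancestor: bool = True) -> DistanceMatrix:
    """Number of SNP positions with unambiguous, differing calls per pair.

    When ``include_ancestor`` is set, the all-ancestral reference is appended
    as an extra taxon so trees can be rooted on it.
    """
    calls = genotypes.calls
    ids = list(genotypes.isolates)
    if include_ancestor:
        calls = np.vstack([calls,
                           np.full((1, calls.shape[1]), ANCESTRAL, np.int8)])
        ids = ids + [ANCESTOR_ID]
    if len(ids) < 2:
        raise ValueError("need at least 2 isolates")
    ok = calls != AMBIGUOUS                       # (n, m) unambiguous mask
    both = ok.astype(np.int64) @ ok.T.astype(np.int64)
    # differing unambiguous calls: exactly one of the pair is DERIVED
    d = (calls == DERIVED).astype(np.int64)
    a = (calls == ANCESTRAL).astype(np.int64)
    diff = d @ a.T + a @ d.T
    dist = diff.astype(float)
    dist[both == 0] = np.nan
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(ids=ids, distances=dist, comparable=both)


def build_nj_tree(dist: DistanceMatrix,
                  root_on_ancestor: bool = True) -> TreeNode:
    """Neighbor-joining tree; negative branch lengths are clamped to zero.

    With fewer than 3 taxa the trivial 2-leaf tree is returned.  Rooting
    places the root on the ancestor's branch (outgroup rooting).
    """
    if dist.has_undefined():
        raise ValueError("distance matrix has undefined entries")
    ids = dist.ids
    if len(ids) == 2:
        d = dist.distances[0, 1]
        tree = TreeNode.read(
            io.StringIO(f"({ids[0]}:{d / 2},{ids[1]}:{d / 2});"))
        return tree
    dm = skbio.DistanceMatrix(dist.distances, ids)
    tree = nj(dm)
    if root_on_ancestor and ANCESTOR_ID in ids:
        tree = tree.root_at(tree.find(ANCESTOR_ID), above=True,
                            reset=True)
    clamped = 0.0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            clamped += -node.length
            node.length = 0.0
    tree.clamped_negative_length = clamped
    return tree


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def dmrca(genotypes: GenotypeMatrix, isolate_subset) -> float:
    """Mean derived-allele count per isolate at within-subset-polymorphic sites.

    Ambiguous calls are excluded both from the polymorphism determination and
    from the per-isolate derived counts.  A single-isolate subset has no
    within-subset polymorphism, hence dMRCA 0.
    """
    subset = list(isolate_subset)
    if not subset:
        raise ValueError("empty isolate subset")
    idx = [genotypes.isolates.index(s) for s in subset]
    sub = genotypes.calls[idx]
    has_anc = (sub == ANCESTRAL).any(axis=0)
    has_der = (sub == DERIVED).any(axis=0)
    polymorphic = has_anc & has_der
    if not polymorphic.any():
        return 0.0
    derived_counts = (sub[:, polymorphic] == DERIVED).sum(axis=1)
    return float(derived_counts.mean())


def mutation_spectrum(snps: list[SnpRecord], weighting: str = "per_snp",
                      genotypes: GenotypeMatrix | None = None,
                      host_of_isolate: dict[str, str] | None = None
                      ) -> pd.DataFrame:
    """Tally substitutions over the six strand-symmetric classes.

    ``per_snp`` counts each SNP once; ``per_isolate`` weights each SNP by the
    number of isolates unambiguously carrying its derived allele (requires a
    genotype matrix).  With host labels the tally is per host and rows
    ``mean``/``sd`` summarise across hosts; otherwise a single ``pooled`` row
    is returned.
    """
    if weighting not in ("per_snp", "per_isolate"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if weighting == "per_isolate" and genotypes is None:
        raise ValueError("per_isolate weighting requires a genotype matrix")

    if host_of_isolate and genotypes is not None:
        hosts = sorted(set(host_of_isolate.values()))
        groups = {h: [i for i, iso in enumerate(genotypes.isolates)
                      if host_of_isolate.get(iso) == h] for h in hosts}
    else:
        hosts = ["pooled"]
        groups = {"pooled": (list(range(len(genotypes.isolates)))
                             if genotypes is not None else None)}

    rows = {}
    for h in hosts:
        tally = dict.fromkeys(MUTATION_CLASSES, 0.0)
        for j, s in enumerate(snps):
            cls = s.mutation_class
            if cls is None:
                raise ValueError(f"{s.snp_id} has no mutation_class")
            if weighting == "per_snp":
                if genotypes is not None and groups[h] is not None:
                    col = genotypes.calls[groups[h], genotypes.column(s.snp_id)]
                    w = 1.0 if (col == DERIVED).any() else 0.0
                else:
                    w = 1.0
            else:
                col = genotypes.calls[groups[h], genotypes.column(s.snp_id)]
                w = float((col == DERIVED).sum())
            tally[cls] += w
        rows[h] = tally
    df = pd.DataFrame(rows).T.reindex(columns=list(MUTATION_CLASSES))
    if len(hosts) > 1:
        df.loc["mean"] = df.loc[hosts].mean()
        df.loc["sd"] = df.loc[hosts].std(ddof=1)
    return df
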