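"""SNP-frequency trajectories, lineage nesting, Muller decomposition, and
cross-host trajectory comparison.

Trajectories are computed from isolate genotypes: the per-day frequency of a
SNP is the number of unambiguously derived isolates over the number of
unambiguously called isolates that day.  SNPs observed derived in fewer than
``min_isolates`` (default 4) isolates overall are dropped as irreproducible.
Missing time points are filled by a monotone-preserving piecewise-cubic
interpolant through the observations, clamped to [0, 1].

Sublineages are nested by SNP-set inclusion (a descendant carries every SNP
of its ancestors) and named E1, E1-A/B, E1-B-1/2...; Muller decomposition
converts raw (cumulative) lineage frequencies into exclusive ones by
subtracting children and clamping at zero.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .io_formats import IsolateRecord
from .variant_core import AMBIGUOUS, DERIVED, GenotypeMatrix

FOUNDER = "founder"


@dataclass
class TrajectorySeries:
    """Observed per-day frequencies of one SNP or lineage."""

    label: str
    days: np.ndarray
    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.days.shape != self.freqs.shape:
            raise ValueError("days and freqs length mismatch")
        if ((self.freqs < 0) | (self.freqs > 1)).any():
            raise ValueError("frequencies outside [0, 1]")
        if not (np.diff(self.days) > 0).all():
            raise ValueError("days must be strictly increasing")


def snp_frequencies(genotypes: GenotypeMatrix,
                    metadata: list[IsolateRecord],
                    min_isolates: int = 4,
                    host_species: str | None = None,
                    subject_id: str | None = None) -> list[TrajectorySeries]:
    """Per-SNP derived-allele frequency series over sampling days.

    Frequencies are pooled over the selected isolates (optionally restricted
    to one host species and/or subject).  Days on which no isolate yields an
    unambiguous call contribute no observation.
    """
    meta = {r.isolate_id: r for r in metadata}
    keep_idx = []
    for i, iso in enumerate(genotypes.isolates):
        rec = meta.get(iso)
        if rec is None:
            continue
        if host_species is not None and rec.host_species != host_species:
            continue
        if subject_id is not None and rec.subject_id != subject_id:
            continue
        keep_idx.append(i)
    days_of = np.array([meta[genotypes.isolates[i]].day for i in keep_idx])
    calls = genotypes.calls[keep_idx]
    all_days = sorted(set(days_of.tolist()))

    out = []
    for j, snp in enumerate(genotypes.snps):
        total_derived = int((genotypes.calls[:, j] == DERIVED).sum())
        if total_derived < min_isolates:
            continue
        days, freqs = [], []
        for d in all_days:
            col = calls[days_of == d, j]
            ok = col != AMBIGUOUS
            if not ok.any():
                continue
            days.append(d)
            freqs.append(float((col[ok] == DERIVED).mean()))
        out.append(TrajectorySeries(label=snp.snp_id,
                                    days=np.array(days, float),
                                    freqs=np.array(freqs, float)))
    return out


def interpolate_trajectory(series: TrajectorySeries,
                           grid_step: float = 0.5
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Dense monotone-preserving cubic curve through the observations.

    The interpolant is exact at observations, stays within [0, 1], and is
    monotone wherever the observations are monotone.  A single observation
    yields a constant curve with a warning.
    """
    days, freqs = series.days, series.freqs
    if len(days) == 0:
        raise ValueError(f"{series.label}: no observations")
    grid = np.arange(days[0], days[-1] + grid_step / 2, grid_step)
    if len(days) == 1:
        warnings.warn(f"{series.label}: single observation; constant curve")
        return np.array([days[0]]), np.array([freqs[0]])
    curve = PchipInterpolator(days, freqs)(grid)
    curve = np.clip(curve, 0.0, 1.0)
    # exactness at observations (pchip is interpolating; enforce bit-exact)
    for d, f in zip(days, freqs):
        curve[np.isclose(grid, d)] = f
    return grid, curve


# ---------------------------------------------------------------------------
# lineage nesting
# ---------------------------------------------------------------------------

@dataclass
class Lineage:
    name: str
    snp_ids: frozenset[str]
    isolates: frozenset[str]
    parent: Optional[str]
    children: list[str] = field(default_factory=list)


@dataclass
class LineageTree:
    """Nested SNP-defined sublineages with per-day raw (cumulative) freqs.

    ``frequencies`` rows are days, columns lineage names; an entry is the
    fraction of that day's isolates belonging to the lineage or any of its
    descendants.  The founder (empty SNP set) is the root.
    """

    nodes: dict[str, Lineage]
    frequencies: pd.DataFrame
    conflicts: list[dict] = field(default_factory=list)

    def children_of(self, name: str) -> list[str]:
        return self.nodes[name].children

    def topology(self) -> set[tuple[frozenset, Optional[frozenset]]]:
        """Order-free description: {(snp set, parent snp set or None)}."""
        out = set()
        for lin in self.nodes.values():
            if lin.name == FOUNDER:
                continue
            parent = self.nodes[lin.parent] if lin.parent else None
            out.add((lin.snp_ids,
                     parent.snp_ids if parent and parent.name != FOUNDER
                     else None))
        return out


def _tolerant_subset(a: frozenset, b: frozenset, tol: float) -> bool:
    """a nested in b, allowing a fraction tol of a's members to violate it."""
    if not a:
        return True
    return len(a - b) <= tol * len(a)


def nest_lineages(genotypes: GenotypeMatrix,
                  metadata: list[IsolateRecord] | None = None,
                  nesting_tolerance: float = 0.10,
                  max_conflict_fraction: float = 0.10) -> LineageTree:
    """Build the nested sublineage tree from derived-isolate sets.

    SNPs with identical derived-isolate sets define one lineage.  Lineages
    are ordered by set inclusion (with a small tolerance for noisy calls and
    majority assignment of violating isolates).  Pairs that overlap without
    inclusion are conflicts; if conflicting isolates exceed
    ``max_conflict_fraction`` of all isolates an error demands curation.
    """
    n_iso = len(genotypes.isolates)
    per_snp: list[tuple[str, frozenset[str]]] = []
    for j, snp in enumerate(genotypes.snps):
        d = genotypes.derived_isolates(j)
        if d:
            per_snp.append((snp.snp_id, d))

    # co-occurring SNPs define one lineage; tolerate a small fraction of
    # noisy (ambiguous) calls when grouping, then take the majority set
    per_snp.sort(key=lambda t: (-len(t[1]), t[0]))
    clusters: list[list[tuple[str, frozenset[str]]]] = []
    for snp_id, d in per_snp:
        for cl in clusters:
            anchor = cl[0][1]
            if len(d ^ anchor) <= nesting_tolerance * max(len(d), len(anchor)):
                cl.append((snp_id, d))
                break
        else:
            clusters.append([(snp_id, d)])
    cands: list[tuple[frozenset[str], frozenset[str]]] = []
    for cl in clusters:
        members = [d for _, d in cl]
        tally: dict[str, int] = {}
        for d in members:
            for iso in d:
                tally[iso] = tally.get(iso, 0) + 1
        majority = frozenset(iso for iso, c in tally.items()
                             if 2 * c >= len(members))
        cands.append((majority, frozenset(s for s, _ in cl)))
    cands.sort(key=lambda t: (-len(t[0]), sorted(t[1])[0]))

    conflicts: list[dict] = []
    conflict_isolates: set[str] = set()
    for (ia, sa), (ib, sb) in itertools.combinations(cands, 2):
        inter = ia & ib
        if not inter:
            continue
        if (_tolerant_subset(ib, ia, nesting_tolerance)
                or _tolerant_subset(ia, ib, nesting_tolerance)):
            continue
        bad = min(ia - ib, ib - ia, key=len) or inter
        conflict_isolates.update(bad)
        conflicts.append({"snps_a": tuple(sorted(sa)),
                          "snps_b": tuple(sorted(sb)),
                          "n_conflicting": len(bad)})
    if n_iso and len(conflict_isolates) > max_conflict_fraction * n_iso:
        raise ValueError(
            f"{len(conflict_isolates)}/{n_iso} isolates violate nesting; "
            f"manual curation required")

    founder = Lineage(name=FOUNDER, snp_ids=frozenset(),
                      isolates=frozenset(genotypes.isolates), parent=None)
    nodes: dict[str, Lineage] = {FOUNDER: founder}
    placed: list[Lineage] = [founder]
    # temporary names; final names assigned after the forest is built
    tmp: list[Lineage] = []
    for iso_set, snp_ids in cands:
        parent = founder
        for cand in sorted(placed, key=lambda l: len(l.isolates)):
            if cand is founder:
                continue
            if _tolerant_subset(iso_set, cand.isolates, nesting_tolerance):
                parent = cand
                break
        # majority assignment: enforce nesting against the chosen parent
        eff = iso_set & parent.isolates if parent is not founder else iso_set
        lin = Lineage(name=f"tmp{len(tmp)}",
                      snp_ids=snp_ids | (parent.snp_ids
                                         if parent is not founder
                                         else frozenset()),
                      isolates=frozenset(eff), parent=parent.name)
        tmp.append(lin)
        placed.append(lin)
        nodes[lin.name] = lin
        parent.children.append(lin.name)

    _assign_names(nodes, FOUNDER)

    freq = pd.DataFrame()
    if metadata is not None:
        meta = {r.isolate_id: r for r in metadata}
        days = sorted({r.day for r in metadata
                       if r.isolate_id in set(genotypes.isolates)})
        rows = {}
        for d in days:
            day_iso = {i for i, r in meta.items()
                       if r.day == d and i in set(genotypes.isolates)}
            if not day_iso:
                continue
            rows[d] = {name: len(lin.isolates & day_iso) / len(day_iso)
                       for name, lin in nodes.items()}
        freq = pd.DataFrame(rows).T.sort_index()
        if FOUNDER in freq.columns:
            freq[FOUNDER] = 1.0  # root is cumulative over everything
    return LineageTree(nodes=nodes, frequencies=freq, conflicts=conflicts)


def _assign_names(nodes: dict[str, Lineage], root: str) -> None:
    """Rename lineages to the E1 / E1-A / E1-B-1 convention, in place."""
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"

    def label(parent: Lineage, k: int, depth: int) -> str:
        if depth == 1:
            return f"E{k + 1}"
        if depth == 2:
            return f"{parent.name}-{letters[k]}"
        return f"{parent.name}-{k + 1}"

    def walk(name: str, depth: int) -> None:
        node = nodes[name]
        kids = sorted(node.children,
                      key=lambda c: (-len(nodes[c].isolates),
                                     sorted(nodes[c].snp_ids)))
        node.children = []
        for k, child in enumerate(kids):
            lin = nodes.pop(child)
            new = label(node, k, depth)
            lin.name = new
            lin.parent = name
            nodes[new] = lin
            node.children.append(new)
            for g in lin.children:
                nodes[g].parent = new
            walk(new, depth + 1)

    walk(root, 1)


def muller_decompose(tree: LineageTree) -> pd.DataFrame:
    """Exclusive per-day lineage frequencies for Muller plotting.

    exclusive(parent) = max(0, raw(parent) - sum of children's raw), the
    clamp encoding that a parent fully displaced by its children keeps
    frequency zero.
    """
    raw = tree.frequencies
    rows = []
    for day, r in raw.iterrows():
        for name, lin in tree.nodes.items():
            if name not in raw.columns:
                continue
            child_sum = sum(r.get(c, 0.0) for c in lin.children)
            rows.append((day, name, max(0.0, float(r[name]) - child_sum)))
    return pd.DataFrame(rows, columns=["day", "lineage", "exclusive_freq"])


# ---------------------------------------------------------------------------
# cross-host comparison (Mantel on Jaccard distances between time points)
# ---------------------------------------------------------------------------

def _jaccard_day_matrix(traj: pd.DataFrame, threshold: float) -> np.ndarray:
    """Jaccard distances between per-day SNP presence sets."""
    days = list(traj.index)
    sets = [frozenset(traj.columns[traj.loc[d] > threshold]) for d in days]
    n = len(days)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            union = sets[i] | sets[j]
            d = 0.0 if not union else 1.0 - len(sets[i] & sets[j]) / len(union)
            out[i, j] = out[j, i] = d
    return out


def mantel_test(x: np.ndarray, y: np.ndarray, n_permutations: int = 9999,
                seed: int | None = None,
                alternative: str = "greater") -> tuple[float, float]:
    """Seeded Mantel test: Pearson correlation of condensed distances with a
    row/column permutation null.  Returns (r, p); r is NaN for a degenerate
    (constant) matrix.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.shape[0] != x.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    iu = np.triu_indices(x.shape[0], 1)
    xv, yv = x[iu], y[iu]
    if xv.std() == 0 or yv.std() == 0:
        return float("nan"), float("nan")
    r = float(np.corrcoef(xv, yv)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    n = x.shape[0]
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        yp = y[np.ix_(perm, perm)][iu]
        rp = float(np.corrcoef(xv, yp)[0, 1])
        if alternative == "greater":
            hit = rp >= r
        elif alternative == "less":
            hit = rp <= r
        else:
            hit = abs(rp) >= abs(r)
        count += hit
    p = (count + 1) / (n_permutations + 1)
    return r, float(p)


def compare_host_dynamics(traj_a: pd.DataFrame, traj_b: pd.DataFrame,
                          n_permutations: int = 9999,
                          seed: int | None = None,
                          freq_threshold: float = 0.0
                          ) -> tuple[float, float]:
    """Mantel correlation between two hosts' SNP-trajectory structures.

    Both inputs are day x SNP frequency tables sharing the same day grid and
    SNP label set.  Each host is summarised as a Jaccard distance matrix
    between its per-day sets of segregating SNPs (frequency > threshold);
    the Mantel statistic compares the two matrices.
    """
    if list(traj_a.index) != list(traj_b.index):
        raise ValueError("hosts must share the same time grid")
    if set(traj_a.columns) != set(traj_b.columns):
        raise ValueError("hosts must share the same SNP label set")
    traj_b = traj_b[traj_a.columns]
    da = _jaccard_day_matrix(traj_a, freq_threshold)
    db = _jaccard_day_matrix(traj_b, freq_threshold)
    return mantel_test(da, db, n_permutations=n_permutations, seed=seed)
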