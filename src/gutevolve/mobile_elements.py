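"""Accessory-contig ("mobile element") identification and presence calling.

Assembled contigs (>= 500 bp) that fail to align to the reference at the
core identity threshold form the accessory genome; mutual deduplication at
the (identity, alignment-fraction) thresholds yields the non-redundant
mobile elements.  Per-isolate presence is then called from read coverage
and depth: present when coverage > 80% AND depth > 60x; absent when
coverage < 20% OR depth < 60x, with the absent rule taking priority where
the two printed rules overlap; anything else is an explicit ``ambiguous``
state rather than a silently invented binary call.

The alignment engine is an injected dependency with a stated contract
(percent identity over the query, alignment length); the bundled default
uses edlib edit-distance alignment, and callers can plug in BLAST/BLAT
style engines for production scale.  The ``evalue`` threshold is carried on
the interface for such engines; the edit-distance engine does not compute
e-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import edlib
import numpy as np
import pandas as pd

from .io_formats import IsolateRecord, ReferenceGenome

PRESENT, ABSENT, AMBIGUOUS_STATE = "present", "absent", "ambiguous"
_RC = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


class AlignmentEngine(Protocol):
    """Contract for the pluggable local-alignment engine."""

    def identity(self, query: str, target: str) -> float:
        """Best percent identity (0..1) of query aligned within target,
        either strand."""
        ...


class EdlibEngine:
    """Edit-distance alignment engine (infix mode, both strands)."""

    def identity(self, query: str, target: str) -> float:
        if not query or not target:
            return 0.0
        best = 0.0
        for q in (query, _revcomp(query)):
            if len(q) <= len(target):
                res = edlib.align(q, target, mode="HW", task="distance")
            else:
                res = edlib.align(target, q, mode="HW", task="distance")
            dist = res["editDistance"]
            if dist >= 0:
                best = max(best, 1.0 - dist / min(len(query), len(target)))
        return best


@dataclass(frozen=True)
class MobileElement:
    element_id: str
    sequence: str
    source_isolates: frozenset[str]

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        if len(self.sequence) < 500:
            raise ValueError(f"{self.element_id}: below the 500 bp contig floor")


@dataclass(frozen=True)
class ElementEvidence:
    element_id: str
    isolate_id: str
    coverage_fraction: float
    mean_depth: float
    state: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage_fraction <= 1.0:
            raise ValueError("coverage_fraction outside [0, 1]")
        if self.mean_depth < 0:
            raise ValueError("negative depth")


def identify_accessory_contigs(isolate_contigs: dict[str, list[str]],
                               reference: ReferenceGenome,
                               engine: AlignmentEngine | None = None,
                               id_core: float = 0.90,
                               evalue: float = 1e-5,
                               id_dedup: float = 0.90,
                               aln_frac: float = 0.85,
                               min_length: int = 500,
                               ) -> list[MobileElement]:
    """Derive the non-redundant accessory genome from per-isolate contigs.

    Contigs matching any reference replicon at >= ``id_core`` identity are
    core and removed; survivors are mutually deduplicated (>= ``id_dedup``
    identity over >= ``aln_frac`` of the longer sequence).  The result is
    invariant to isolate input order.
    """
    engine = engine or EdlibEngine()
    # pool unique contig sequences with their source isolates, deterministically
    sources: dict[str, set[str]] = {}
    for iso in sorted(isolate_contigs):
        for contig in isolate_contigs[iso]:
            contig = contig.upper()
            if len(contig) < min_length:
                continue
            sources.setdefault(contig, set()).add(iso)
    if not sources:
        return []

    refs = list(reference.replicons.values())
    accessory = []
    for contig in sorted(sources, key=lambda c: (-len(c), c)):
        if max(engine.identity(contig, r) for r in refs) >= id_core:
            continue  # core genome
        accessory.append(contig)

    # greedy dedup against accepted representatives (longest first)
    reps: list[tuple[str, set[str]]] = []
    for contig in accessory:
        matched = False
        for rep_seq, rep_src in reps:
            short, long_ = sorted((contig, rep_seq), key=len)
            if (len(short) >= aln_frac * len(long_)
                    and engine.identity(short, long_) >= id_dedup):
                rep_src.update(sources[contig])
                matched = True
                break
        if not matched:
            reps.append((contig, set(sources[contig])))
    return [MobileElement(element_id=f"ME{i + 1:03d}", sequence=seq,
                          source_isolates=frozenset(src))
            for i, (seq, src) in enumerate(reps)]


def call_presence(coverage_fraction: float, mean_depth: float,
                  presence_min_coverage: float = 0.80,
                  absence_max_coverage: float = 0.20,
                  min_depth: float = 60.0) -> str:
    """Presence call from read coverage and depth; absent rule wins overlaps."""
    if not 0.0 <= coverage_fraction <= 1.0:
        raise ValueError("coverage_fraction outside [0, 1]")
    if coverage_fraction < absence_max_coverage or mean_depth < min_depth:
        return ABSENT
    if coverage_fraction > presence_min_coverage and mean_depth > min_depth:
        return PRESENT
    return AMBIGUOUS_STATE


def score_elements(elements: list[MobileElement],
                   coverage: dict[tuple[str, str], tuple[float, float]],
                   **thresholds) -> list[ElementEvidence]:
    """Call presence for every (element, isolate) coverage/depth pair.

    ``coverage`` maps (element_id, isolate_id) -> (coverage_fraction, depth).
    """
    out = []
    for (eid, iso), (cov, depth) in sorted(coverage.items()):
        out.append(ElementEvidence(
            element_id=eid, isolate_id=iso, coverage_fraction=cov,
            mean_depth=depth, state=call_presence(cov, depth, **thresholds)))
    return out


def element_trajectory(evidence: list[ElementEvidence],
                       metadata: list[IsolateRecord]) -> pd.DataFrame:
    """Per (element, host, day) presence frequency and log10 depth.

    Frequency is present / (present + absent); when every isolate of a day is
    ambiguous the frequency is reported missing (NaN), not 0.
    """
    meta = {r.isolate_id: r for r in metadata}
    rows = []
    for ev in evidence:
        rec = meta.get(ev.isolate_id)
        if rec is None:
            continue
        rows.append((ev.element_id, rec.host_species, rec.day, ev.state,
                     ev.mean_depth))
    df = pd.DataFrame(rows, columns=["element_id", "host", "day", "state",
                                     "depth"])
    out = []
    for (eid, host, day), grp in df.groupby(["element_id", "host", "day"]):
        n_present = int((grp["state"] == PRESENT).sum())
        n_absent = int((grp["state"] == ABSENT).sum())
        denom = n_present + n_absent
        freq = n_present / denom if denom else np.nan
        with np.errstate(divide="ignore"):
            log_depth = float(np.log10(grp["depth"].clip(lower=0.1)).mean())
        out.append((eid, host, day, freq, len(grp), log_depth))
    return pd.DataFrame(out, columns=["element_id", "host", "day",
                                      "freq_present", "n_isolates",
                                      "mean_log10_depth"])
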