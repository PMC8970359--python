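"""Per-protein domain architectures, homolog filters and class taxonomy.

Overlapping calls of the same domain type (database scan, motif regex,
secondary-structure annotation) are summarised into single instances; CdvC
candidates are filtered for a genuine Vps4_C or MIT region (the AAA+ ATPase
region alone is spread across many unrelated proteins); CdvB homologs are
assigned to the classes observed in TACK archaea (CdvB, CdvB1/2, CdvB3) or,
for Asgard, the two clades CdvBa1/CdvBa2 distinguished by the ANCHR helix.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .types import (
    AnnotationRow,
    ArchitectureTable,
    DomainInstance,
    DomainType,
    EVIDENCE_RANK,
    Evidence,
    Family,
    MotifMatch,
    ProteinArchitecture,
    SequenceRecord,
    SuperPhylum,
)

__all__ = [
    "ArchitectureClass",
    "assemble_architectures",
    "filter_cdvc",
    "classify_cdvb",
    "shared_domains",
    "organisms_with_homologs",
    "gene_neighborhood",
]


class ArchitectureClass(str, Enum):
    CDVB = "CdvB_class"
    CDVB12 = "CdvB12_class"
    CDVB3 = "CdvB3_class"
    CDVBA1 = "CdvBa1"
    CDVBA2 = "CdvBa2"
    UNCLASSIFIED = "unclassified"


# MIM2 class precedence when deduplicating motif matches on one protein.
_MIM2_PRECEDENCE = {"MIM2_total": 3, "MIM2_Sulf": 2, "MIM2_Core": 1, "putative_MIM2": 0}


def _merge_same_type(instances: list[DomainInstance]) -> list[DomainInstance]:
    """Union-merge overlapping instances of one domain type."""
    instances = sorted(instances, key=lambda d: (d.start, d.end))
    merged: list[DomainInstance] = []
    for inst in instances:
        if merged and inst.start <= merged[-1].end:
            prev = merged[-1]
            prev.end = max(prev.end, inst.end)
            if EVIDENCE_RANK[inst.evidence] > EVIDENCE_RANK[prev.evidence]:
                prev.evidence = inst.evidence
            if inst.proline_count is not None:
                prev.proline_count = max(prev.proline_count or 0, inst.proline_count)
        else:
            merged.append(
                DomainInstance(
                    domain_type=inst.domain_type,
                    start=inst.start,
                    end=inst.end,
                    evidence=inst.evidence,
                    qualifier=inst.qualifier,
                    proline_count=inst.proline_count,
                )
            )
    return merged


def assemble_architectures(
    annotations: Iterable[AnnotationRow],
    motif_matches: Iterable[MotifMatch] = (),
    sequences: Optional[Sequence[SequenceRecord]] = None,
    families: Optional[Mapping[str, Family]] = None,
) -> list[ProteinArchitecture]:
    """Summarise per-protein domain calls into merged architectures.

    Overlapping same-type calls become one instance spanning their union with
    the strongest contributing evidence. MIM2 motif matches are deduplicated
    to a single MIM2 instance per protein, preferring the most complete motif
    class (total > Sulf > Core > putative) and, within a class, the match with
    most prolines. Family labels come from ``families`` (or stay unassigned);
    organism metadata comes from ``sequences``.
    """
    seq_by_id = {s.id: s for s in sequences} if sequences is not None else None

    per_protein: dict[str, list[DomainInstance]] = defaultdict(list)
    for ann in annotations:
        if seq_by_id is not None:
            if ann.protein_id not in seq_by_id:
                raise KeyError(
                    f"annotation references unknown protein {ann.protein_id!r}"
                )
            if ann.end > len(seq_by_id[ann.protein_id].residues):
                raise ValueError(
                    f"{ann.protein_id}: annotation {ann.domain_type.value} ends at "
                    f"{ann.end}, beyond sequence length"
                )
        per_protein[ann.protein_id].append(
            DomainInstance(ann.domain_type, ann.start, ann.end, ann.evidence)
        )

    mim2_best: dict[str, MotifMatch] = {}
    for mm in motif_matches:
        if seq_by_id is not None and mm.protein_id not in seq_by_id:
            raise KeyError(f"motif match references unknown protein {mm.protein_id!r}")
        key = mm.protein_id
        cur = mim2_best.get(key)
        rank = (_MIM2_PRECEDENCE.get(mm.pattern, 0), mm.proline_count, -mm.start)
        if cur is None or rank > (
            _MIM2_PRECEDENCE.get(cur.pattern, 0), cur.proline_count, -cur.start
        ):
            mim2_best[key] = mm
    for pid, mm in mim2_best.items():
        per_protein[pid].append(
            DomainInstance(
                DomainType.MIM2,
                mm.start,
                mm.end,
                mm.evidence,
                qualifier=mm.pattern,
                proline_count=mm.proline_count,
            )
        )

    ids = sorted(per_protein)
    if seq_by_id is not None:
        ids = sorted(set(ids) | set(seq_by_id))  # keep call-free proteins
    out: list[ProteinArchitecture] = []
    for pid in ids:
        by_type: dict[DomainType, list[DomainInstance]] = defaultdict(list)
        for inst in per_protein.get(pid, []):
            by_type[inst.domain_type].append(inst)
        domains: list[DomainInstance] = []
        for dtype in sorted(by_type, key=lambda d: d.value):
            domains.extend(_merge_same_type(by_type[dtype]))
        seq = seq_by_id.get(pid) if seq_by_id else None
        out.append(
            ProteinArchitecture(
                protein_id=pid,
                family=(families or {}).get(pid, Family.UNASSIGNED),
                organism=seq.organism if seq else None,
                super_phylum=seq.super_phylum if seq else None,
                domains=domains,
            )
        )
    return out


@dataclass
class FilterVerdict:
    protein: ProteinArchitecture
    reason: str


def filter_cdvc(
    candidates: Iterable[ProteinArchitecture],
    allowlist: frozenset[str] | set[str] = frozenset(),
) -> tuple[list[FilterVerdict], list[FilterVerdict]]:
    """Keep CdvC candidates with a genuine Vps4_C or MIT region.

    The AAA+ ATPase region alone occurs in many unrelated proteins, so
    ATPase-only candidates are rejected unless explicitly allowlisted
    (the published survey grants one such exception on homology-search
    E-value grounds). Both lists carry per-protein reason strings.
    """
    kept: list[FilterVerdict] = []
    rejected: list[FilterVerdict] = []
    for cand in candidates:
        if cand.has(DomainType.VPS4_C) or cand.has(DomainType.MIT):
            found = sorted(
                d.value
                for d in cand.domain_types & {DomainType.VPS4_C, DomainType.MIT}
            )
            kept.append(FilterVerdict(cand, f"has {'/'.join(found)}"))
        elif cand.protein_id in allowlist:
            kept.append(FilterVerdict(cand, "allowlist"))
        else:
            present = sorted(d.value for d in cand.domain_types) or ["none"]
            rejected.append(
                FilterVerdict(
                    cand, f"no Vps4_C or MIT region (has: {', '.join(present)})"
                )
            )
    return kept, rejected


def classify_cdvb(arch: ProteinArchitecture) -> ArchitectureClass:
    """Assign a CdvB homolog to its architecture class.

    TACK homologs: CdvB = {Snf7, MIM2, BWH}; CdvB1/2 = {Snf7, MIM2} without
    BWH; CdvB3 = Snf7 only. Asgard homologs split into CdvBa1 (ANCHR-bearing)
    and CdvBa2 (Snf7 without ANCHR). Anything else is unclassified, never
    forced.
    """
    doms = arch.domain_types
    if arch.super_phylum is SuperPhylum.ASGARD:
        if DomainType.SNF7 in doms and DomainType.ANCHR in doms:
            return ArchitectureClass.CDVBA1
        if DomainType.SNF7 in doms and DomainType.ANCHR not in doms:
            return ArchitectureClass.CDVBA2
        return ArchitectureClass.UNCLASSIFIED
    if arch.super_phylum is not None and not arch.super_phylum.is_tack:
        return ArchitectureClass.UNCLASSIFIED
    if arch.has(DomainType.SNF7, DomainType.MIM2, DomainType.BWH):
        return ArchitectureClass.CDVB
    if (
        arch.has(DomainType.SNF7, DomainType.MIM2)
        and DomainType.BWH not in doms
        and DomainType.ANCHR not in doms
    ):
        return ArchitectureClass.CDVB12
    if doms == {DomainType.SNF7}:
        return ArchitectureClass.CDVB3
    return ArchitectureClass.UNCLASSIFIED


def shared_domains(
    table: ArchitectureTable, groups: Mapping[str, Sequence[str]]
) -> set[DomainType]:
    """Domain types present in at least one organism of *every* group."""
    assigned: set[str] = set()
    for name, members in groups.items():
        if not members:
            raise ValueError(f"group {name!r} is empty")
        overlap = assigned & set(members)
        if overlap:
            raise ValueError(f"organisms assigned to multiple groups: {sorted(overlap)}")
        assigned |= set(members)
    shared: Optional[set[DomainType]] = None
    for members in groups.values():
        union = table.domain_union(members)
        shared = union if shared is None else shared & union
    return shared or set()


def organisms_with_homologs(table: ArchitectureTable) -> tuple[int, int]:
    """Count organisms with >=1 protein of family CdvA/CdvB/CdvC vs without."""
    if not table.organisms:
        raise ValueError("architecture table lists no organisms")
    families = {Family.CDVA, Family.CDVB, Family.CDVC}
    with_homolog = 0
    for org in table.organisms:
        if any(p.family in families for p in table.proteins_of(org)):
            with_homolog += 1
    return with_homolog, len(table.organisms) - with_homolog


def gene_neighborhood(
    coords: pd.DataFrame,
    families: Mapping[str, Family | str],
    direct_k: int = 1,
    close_k: int = 5,
) -> dict[str, str]:
    """Bucket each organism by how tightly its Cdv genes cluster.

    ``coords`` needs columns organism, gene_id, start (genomic); gene rank
    order per organism is derived from start positions. The minimal pairwise
    rank distance among Cdv genes maps to ``direct`` (<= direct_k),
    ``close`` (<= close_k) or ``distant``; organisms with fewer than two Cdv
    genes are ``absent``. Thresholds are package defaults.
    """
    required = {"organism", "gene_id", "start"}
    missing = required - set(coords.columns)
    if missing:
        raise ValueError(f"coordinate table missing column(s) {sorted(missing)}")
    fam_lookup = {g: (Family(f) if isinstance(f, str) else f) for g, f in families.items()}
    out: dict[str, str] = {}
    for organism, sub in coords.groupby("organism", sort=False):
        if sub["start"].duplicated().any():
            raise ValueError(f"{organism}: duplicate gene coordinates")
        ordered = sub.sort_values("start").reset_index(drop=True)
        ranks = [
            i for i, gid in enumerate(ordered["gene_id"]) if gid in fam_lookup
        ]
        if len(ranks) < 2:
            out[organism] = "absent"
            continue
        min_dist = min(b - a for a, b in zip(ranks, ranks[1:]))
        if min_dist <= direct_k:
            out[organism] = "direct"
        elif min_dist <= close_k:
            out[organism] = "close"
        else:
            out[organism] = "distant"
    return out
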