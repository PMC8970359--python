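"""Core data containers shared across the toolkit.

The unit of analysis is the *domain architecture*: a protein abstracted as an
ordered list of domains/motifs, each with 1-based inclusive coordinates and an
evidence class. Eleven domain types make up the closed vocabulary observed in
archaeal Cdv (cell-division) machineries; architectures built from them feed
the interaction-network, mechanism-inference and ancestral-reconstruction
stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Optional, Sequence

__all__ = [
    "SuperPhylum",
    "Family",
    "DomainType",
    "Evidence",
    "EVIDENCE_RANK",
    "VALID_RESIDUES",
    "SequenceRecord",
    "AnnotationRow",
    "SecondaryStructureTrack",
    "DomainInstance",
    "ProteinArchitecture",
    "ArchitectureTable",
    "MotifMatch",
    "HelixCall",
    "TreeNode",
    "RootedTree",
    "PresenceMatrix",
]

# 20 standard amino acids plus X for unknown residues.
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class SuperPhylum(str, Enum):
    EURYARCHAEOTA = "Euryarchaeota"
    ASGARD = "Asgard"
    TACK_CRENARCHAEOTA = "TACK_Crenarchaeota"
    TACK_THAUMARCHAEOTA = "TACK_Thaumarchaeota"
    OTHER = "other"

    @property
    def is_tack(self) -> bool:
        return self in (SuperPhylum.TACK_CRENARCHAEOTA, SuperPhylum.TACK_THAUMARCHAEOTA)


class Family(str, Enum):
    CDVA = "CdvA"
    CDVB = "CdvB"
    CDVC = "CdvC"
    UNASSIGNED = "unassigned"


class DomainType(str, Enum):
    """The eleven building blocks found in archaeal Cdv machineries."""

    CDVA_ALPHA = "CdvA_alpha"
    CDVA_BETA = "CdvA_beta"
    BWI = "BWI"
    BWH = "BWH"
    MIM1 = "MIM1"
    MIM2 = "MIM2"
    SNF7 = "Snf7"
    VPS4_C = "Vps4_C"
    MIT = "MIT"
    AAA_ATPASE = "AAA_ATPase"
    ANCHR = "ANCHR"


class Evidence(str, Enum):
    DB_SCAN = "db_scan"
    MOTIF_REGEX = "motif_regex"
    SS_ANNOTATION = "ss_annotation"
    PUTATIVE = "putative"


# Higher value = stronger evidence; merged instances keep the strongest.
EVIDENCE_RANK = {
    Evidence.DB_SCAN: 3,
    Evidence.MOTIF_REGEX: 2,
    Evidence.SS_ANNOTATION: 1,
    Evidence.PUTATIVE: 0,
}


@dataclass
class SequenceRecord:
    id: str
    residues: str
    organism: Optional[str] = None
    super_phylum: Optional[SuperPhylum] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be nonempty")
        self.residues = self.residues.upper()
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid residue symbol(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AnnotationRow:
    protein_id: str
    domain_type: DomainType
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    evidence: Evidence
    source: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"{self.protein_id}/{self.domain_type.value}: "
                f"invalid coordinates {self.start}..{self.end}"
            )


@dataclass
class SecondaryStructureTrack:
    protein_id: str
    ss: str  # one of H/E/C per residue

    def __post_init__(self) -> None:
        bad = set(self.ss) - set("HEC")
        if bad:
            raise ValueError(
                f"{self.protein_id}: secondary-structure symbols must be H/E/C, "
                f"got {sorted(bad)}"
            )


@dataclass
class DomainInstance:
    """One called domain or motif on a protein."""

    domain_type: DomainType
    start: int
    end: int
    evidence: Evidence
    qualifier: Optional[str] = None  # e.g. MIM2 class: "total" / "Sulf" / "Core"
    proline_count: Optional[int] = None

    def overlaps(self, other: "DomainInstance") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass
class ProteinArchitecture:
    protein_id: str
    family: Family = Family.UNASSIGNED
    organism: Optional[str] = None
    super_phylum: Optional[SuperPhylum] = None
    domains: list[DomainInstance] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.domains.sort(key=lambda d: (d.start, d.end, d.domain_type.value))

    @property
    def domain_types(self) -> frozenset[DomainType]:
        return frozenset(d.domain_type for d in self.domains)

    def has(self, *types: DomainType) -> bool:
        present = self.domain_types
        return all(t in present for t in types)

    def instance(self, domain_type: DomainType) -> Optional[DomainInstance]:
        for d in self.domains:
            if d.domain_type is domain_type:
                return d
        return None


@dataclass
class ArchitectureTable:
    """All proteins of a study set, plus organisms that have no Cdv homolog.

    ``organisms`` preserves the input order (e.g. phylogenetic order of a
    figure); organisms without any protein appear there but have no entry in
    ``proteins``.
    """

    proteins: list[ProteinArchitecture] = field(default_factory=list)
    organisms: list[str] = field(default_factory=list)
    super_phyla: dict[str, SuperPhylum] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = list(dict.fromkeys(self.organisms))
        for p in self.proteins:
            if p.organism and p.organism not in seen:
                seen.append(p.organism)
            if p.organism and p.super_phylum and p.organism not in self.super_phyla:
                self.super_phyla[p.organism] = p.super_phylum
        self.organisms = seen

    def proteins_of(self, organism: str) -> list[ProteinArchitecture]:
        return [p for p in self.proteins if p.organism == organism]

    def domain_union(self, organisms: Optional[Sequence[str]] = None) -> set[DomainType]:
        pool = set(organisms) if organisms is not None else set(self.organisms)
        out: set[DomainType] = set()
        for p in self.proteins:
            if p.organism in pool:
                out |= p.domain_types
        return out


@dataclass(frozen=True)
class MotifMatch:
    protein_id: str
    pattern: str  # MotifPattern name or "putative_MIM2"
    start: int
    end: int
    matched_span: str
    proline_count: int
    evidence: Evidence = Evidence.MOTIF_REGEX


@dataclass(frozen=True)
class HelixCall:
    protein_id: str
    region_start: int
    region_end: int
    is_helix: bool
    has_proline: bool

    @property
    def anchr_call(self) -> bool:
        return self.is_helix and not self.has_proline


class TreeNode:
    """Node of a rooted tree; polytomies allowed."""

    __slots__ = ("label", "children", "parent")

    def __init__(self, label: str, children: Optional[list["TreeNode"]] = None):
        self.label = label
        self.children: list[TreeNode] = children or []
        self.parent: Optional[TreeNode] = None
        for c in self.children:
            c.parent = self

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.label!r}, n_children={len(self.children)})"


class RootedTree:
    """A rooted tree with uniquely labelled leaves.

    Internal nodes without a Newick label are auto-named ``n0, n1, ...`` in
    preorder so reconstructions can address every node deterministically.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        counter = 0
        labels: set[str] = set()
        for node in self.preorder():
            if not node.label:
                while f"n{counter}" in labels:
                    counter += 1
                node.label = f"n{counter}"
                counter += 1
            if node.label in labels:
                raise ValueError(f"duplicate node label {node.label!r}")
            labels.add(node.label)
        self._by_label = {n.label: n for n in self.preorder()}

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        yield from reversed(out)

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def node(self, label: str) -> TreeNode:
        try:
            return self._by_label[label]
        except KeyError:
            raise KeyError(f"no node labelled {label!r} in tree") from None

    def branches(self) -> Iterator[tuple[TreeNode, TreeNode]]:
        """(parent, child) pairs, preorder."""
        for node in self.preorder():
            for child in node.children:
                yield node, child

    def to_newick(self) -> str:
        def render(node: TreeNode) -> str:
            if node.is_leaf:
                return node.label
            inner = ",".join(render(c) for c in node.children)
            return f"({inner}){node.label}"

        return render(self.root) + ";"


@dataclass
class PresenceMatrix:
    """Binary taxa x characters matrix of domain presence/absence.

    Characters may be family-qualified (``"CdvB:MIM2"``) because the same
    domain type carried by different families evolves independently.
    """

    taxa: list[str]
    characters: list[str]
    states: list[list[int]]  # row per taxon

    def __post_init__(self) -> None:
        if len(self.states) != len(self.taxa):
            raise ValueError("one state row per taxon required")
        for taxon, row in zip(self.taxa, self.states):
            if len(row) != len(self.characters):
                raise ValueError(f"row for {taxon!r} has wrong length")
            if any(s not in (0, 1) for s in row):
                raise ValueError(f"row for {taxon!r} contains non-binary states")
        self._row = {t: i for i, t in enumerate(self.taxa)}
        self._col = {c: j for j, c in enumerate(self.characters)}

    def state(self, taxon: str, character: str) -> int:
        try:
            return self.states[self._row[taxon]][self._col[character]]
        except KeyError as exc:
            raise KeyError(f"unknown taxon or character: {exc}") from None

    def column(self, character: str) -> dict[str, int]:
        j = self._col[character]
        return {t: self.states[i][j] for t, i in self._row.items()}
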