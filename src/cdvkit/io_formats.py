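"""Readers and writers for the external formats the pipeline touches.

Sequences travel as FASTA (via Biopython), trees as Newick (via dendropy),
tables as TSV (via pandas). A pipe-delimited FASTA header dialect
(``id|organism|super_phylum``) carries per-organism metadata; plain headers
degrade gracefully to id-only records.

Packaged fixtures transcribe the published figures of the Cdv/ESCRT domain
survey (architecture table, Asgard helix alignment, presence/absence matrix
and its tree) so every stage runs without downloads.
"""

from __future__ import annotations

import io
from importlib import resources
from pathlib import Path
from typing import Union

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .types import (
    AnnotationRow,
    ArchitectureTable,
    DomainInstance,
    DomainType,
    Evidence,
    Family,
    PresenceMatrix,
    RootedTree,
    SecondaryStructureTrack,
    SequenceRecord,
    SuperPhylum,
    TreeNode,
)

PathLike = Union[str, Path]

ANNOTATION_COLUMNS = ["protein_id", "domain_type", "start", "end", "evidence", "source"]

FIXTURE_NAMES = ("fig1_architectures", "fig5_asgard", "fig6_matrix", "fig6_tree")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _parse_header(header: str) -> tuple[str, str | None, SuperPhylum | None]:
    parts = header.split("|")
    if len(parts) >= 3:
        phylum = SuperPhylum(parts[2].strip())
        return parts[0].strip(), parts[1].strip() or None, phylum
    return parts[0].strip(), None, None


def read_fasta(path: PathLike) -> list[SequenceRecord]:
    """Read FASTA into SequenceRecords, uppercasing and validating residues."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        rec_id, organism, phylum = _parse_header(entry.description or entry.id)
        if rec_id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec_id!r}")
        seen.add(rec_id)
        records.append(
            SequenceRecord(
                id=rec_id,
                residues=str(entry.seq),
                organism=organism,
                super_phylum=phylum,
            )
        )
    return records


def write_fasta(records: list[SequenceRecord], path: PathLike) -> None:
    entries = []
    for rec in records:
        if rec.organism and rec.super_phylum:
            header = f"{rec.id}|{rec.organism}|{rec.super_phylum.value}"
        else:
            header = rec.id
        entries.append(BioSeqRecord(Seq(rec.residues), id=header, description=""))
    SeqIO.write(entries, str(path), "fasta")


# ---------------------------------------------------------------------------
# Annotation / secondary-structure TSV
# ---------------------------------------------------------------------------

def read_annotations(path: PathLike, strict: bool = True) -> list[AnnotationRow]:
    """Read a domain-annotation TSV (InterProScan/CDD-style summary).

    In strict mode a ``domain_type`` outside the 11-entry vocabulary is an
    error; in lenient mode such rows are silently dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in ANNOTATION_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    vocabulary = sorted(d.value for d in DomainType)
    rows: list[AnnotationRow] = []
    for _, r in df.iterrows():
        try:
            dtype = DomainType(r["domain_type"])
        except ValueError:
            if strict:
                raise ValueError(
                    f"{path}: unknown domain_type {r['domain_type']!r} for "
                    f"{r['protein_id']!r}; allowed: {vocabulary}"
                ) from None
            continue
        rows.append(
            AnnotationRow(
                protein_id=r["protein_id"],
                domain_type=dtype,
                start=int(r["start"]),
                end=int(r["end"]),
                evidence=Evidence(r["evidence"]),
                source=r.get("source", ""),
            )
        )
    return rows


def write_annotations(rows: list[AnnotationRow], path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "protein_id": r.protein_id,
                "domain_type": r.domain_type.value,
                "start": r.start,
                "end": r.end,
                "evidence": r.evidence.value,
                "source": r.source,
            }
            for r in rows
        ],
        columns=ANNOTATION_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_ss_tracks(path: PathLike) -> list[SecondaryStructureTrack]:
    """Read per-residue secondary-structure strings (columns protein_id, ss)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        SecondaryStructureTrack(protein_id=r["protein_id"], ss=r["ss"])
        for _, r in df.iterrows()
    ]


def write_ss_tracks(tracks: list[SecondaryStructureTrack], path: PathLike) -> None:
    pd.DataFrame(
        [{"protein_id": t.protein_id, "ss": t.ss} for t in tracks]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def _convert(node: dendropy.Node) -> TreeNode:
    label = None
    if node.taxon is not None and node.taxon.label:
        label = node.taxon.label
    elif node.label:
        label = node.label
    out = TreeNode(label or "")
    for child in node.child_nodes():
        out.add(_convert(child))
    return out


def read_newick(path: PathLike) -> RootedTree:
    """Parse a Newick file into a RootedTree; polytomies are preserved."""
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    return RootedTree(_convert(tree.seed_node))


def parse_newick(newick: str) -> RootedTree:
    """Parse a Newick string (same semantics as :func:`read_newick`)."""
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    return RootedTree(_convert(tree.seed_node))


# ---------------------------------------------------------------------------
# Architecture tables
# ---------------------------------------------------------------------------

_SENTINEL = "-"


def _architecture_table_from_df(df: pd.DataFrame) -> ArchitectureTable:
    from .types import ProteinArchitecture

    organisms: list[str] = []
    phyla: dict[str, SuperPhylum] = {}
    builders: dict[str, ProteinArchitecture] = {}
    for _, r in df.iterrows():
        organism = r["organism"]
        phylum = SuperPhylum(r["super_phylum"])
        if organism not in organisms:
            organisms.append(organism)
            phyla[organism] = phylum
        if r["protein_id"] == _SENTINEL:
            continue  # organism listed with no Cdv homolog
        pid = r["protein_id"]
        if pid not in builders:
            builders[pid] = ProteinArchitecture(
                protein_id=pid,
                family=Family(r["family"]),
                organism=organism,
                super_phylum=phylum,
            )
        if r["domain_type"] != _SENTINEL:
            builders[pid].domains.append(
                DomainInstance(
                    domain_type=DomainType(r["domain_type"]),
                    start=int(r["start"]),
                    end=int(r["end"]),
                    evidence=Evidence(r["evidence"]),
                )
            )
    table = ArchitectureTable(
        proteins=list(builders.values()), organisms=organisms, super_phyla=phyla
    )
    for p in table.proteins:
        p.domains.sort(key=lambda d: (d.start, d.end, d.domain_type.value))
    return table


def read_architecture_table(path: PathLike) -> ArchitectureTable:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna(_SENTINEL)
    return _architecture_table_from_df(df)


def write_architecture_table(table: ArchitectureTable, path: PathLike) -> None:
    rows = []
    for org in table.organisms:
        prots = table.proteins_of(org)
        phylum = table.super_phyla.get(org, SuperPhylum.OTHER).value
        if not prots:
            rows.append(
                dict(organism=org, super_phylum=phylum, protein_id=_SENTINEL,
                     family=_SENTINEL, domain_type=_SENTINEL, start=_SENTINEL,
                     end=_SENTINEL, evidence=_SENTINEL)
            )
        for p in prots:
            if not p.domains:
                rows.append(
                    dict(organism=org, super_phylum=phylum, protein_id=p.protein_id,
                         family=p.family.value, domain_type=_SENTINEL,
                         start=_SENTINEL, end=_SENTINEL, evidence=_SENTINEL)
                )
            for d in p.domains:
                rows.append(
                    dict(organism=org, super_phylum=phylum, protein_id=p.protein_id,
                         family=p.family.value, domain_type=d.domain_type.value,
                         start=d.start, end=d.end, evidence=d.evidence.value)
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Presence matrices
# ---------------------------------------------------------------------------

def read_presence_matrix(path: PathLike) -> PresenceMatrix:
    df = pd.read_csv(path, sep="\t", comment="#")
    taxa = df.iloc[:, 0].astype(str).tolist()
    characters = list(df.columns[1:])
    states = df.iloc[:, 1:].astype(int).values.tolist()
    return PresenceMatrix(taxa=taxa, characters=characters, states=states)


def write_presence_matrix(matrix: PresenceMatrix, path: PathLike) -> None:
    df = pd.DataFrame(matrix.states, columns=matrix.characters)
    df.insert(0, "taxon", matrix.taxa)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def _fixture_text(filename: str) -> str:
    return (resources.files("cdvkit.fixtures") / filename).read_text()


def load_fixture(name: str):
    """Load a packaged figure transcription.

    * ``fig1_architectures`` -> :class:`ArchitectureTable` (51 organisms)
    * ``fig5_asgard`` -> list of ``(SequenceRecord, SecondaryStructureTrack,
      clade)`` tuples for the Asgard CdvB N-termini
    * ``fig6_matrix`` -> :class:`PresenceMatrix` (family-qualified characters)
    * ``fig6_tree`` -> :class:`RootedTree` over the four archaeal groups
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    if name == "fig1_architectures":
        df = pd.read_csv(
            io.StringIO(_fixture_text("fig1_architectures.tsv")),
            sep="\t", dtype=str, comment="#",
        ).fillna(_SENTINEL)
        return _architecture_table_from_df(df)
    if name == "fig5_asgard":
        df = pd.read_csv(
            io.StringIO(_fixture_text("fig5_asgard.tsv")),
            sep="\t", dtype=str, comment="#",
        )
        out = []
        for _, r in df.iterrows():
            rec = SequenceRecord(
                id=r["protein_id"],
                residues=r["sequence"],
                organism=r["organism"],
                super_phylum=SuperPhylum.ASGARD,
            )
            track = SecondaryStructureTrack(protein_id=r["protein_id"], ss=r["ss"])
            if len(track.ss) != len(rec.residues):
                raise ValueError(f"fixture row {rec.id}: ss/sequence length mismatch")
            out.append((rec, track, r["clade"]))
        return out
    if name == "fig6_matrix":
        return read_presence_matrix(
            io.StringIO(_fixture_text("fig6_matrix.tsv"))
        )
    return parse_newick(_fixture_text("fig6_tree.nwk").strip())
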