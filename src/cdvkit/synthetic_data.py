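"""Synthetic inputs with the statistical structure the pipeline assumes.

Two generators: (i) random protein sequences with motifs planted from the
MIM2 templates (φ/x positions sampled uniformly from their residue classes,
literal P positions always proline) plus optional ANCHR-style helix tracks;
(ii) binary domain characters evolved root→leaves along a rooted tree with
per-branch gain/loss probabilities. Both are fully determined by their seed.

Background residues are drawn i.i.d. and uniformly — a deliberately simple
null (no archaeal composition bias, no indels, no substitution process), so
planted-motif recall is 1.0 by construction and precision is 1.0 whenever
the background excludes proline (all MIM2 templates contain literal P).

``make_paper_protein_sets`` returns the three ancestral protein complements
(Crenarchaeota, Thaumarchaeota, Asgard) whose interactions the mechanism
engine explains; MIM2 proline counts encode the observed CdvB (4) vs
CdvB1/2 (2) difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .motif_scan import PATTERNS, PHI_ALPHABET, X_ALPHABET, MotifPattern
from .types import (
    DomainInstance,
    DomainType,
    Evidence,
    Family,
    MotifMatch,
    PresenceMatrix,
    ProteinArchitecture,
    RootedTree,
    SecondaryStructureTrack,
    SequenceRecord,
    SuperPhylum,
)

__all__ = [
    "SequenceSimSpec",
    "EvolSimSpec",
    "generate_sequences",
    "simulate_domain_evolution",
    "make_paper_protein_sets",
]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SequenceSimSpec:
    n_proteins: int
    length_range: tuple[int, int] = (80, 200)
    exclude_proline_background: bool = False
    # (pattern name, position policy) pairs; every protein gets each plant
    planted: tuple[tuple[str, str], ...] = ()
    plant_anchr: Optional[bool] = None  # None = no helix track planting
    anchr_with_proline: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid length range")
        for name, policy in self.planted:
            if name not in PATTERNS:
                raise KeyError(f"unknown pattern {name!r}")
            if policy not in ("nterm", "cterm", "uniform"):
                raise ValueError(f"unknown position policy {policy!r}")
            if len(PATTERNS[name]) > lo:
                raise ValueError(
                    f"planted span {name} ({len(PATTERNS[name])}) exceeds "
                    f"minimum length {lo}"
                )


@dataclass(frozen=True)
class EvolSimSpec:
    tree: RootedTree
    characters: tuple[str, ...]
    root_states: tuple[int, ...]
    gain_prob: float = 0.0
    loss_prob: float = 0.1
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.characters) != len(self.root_states):
            raise ValueError("one root state per character required")
        for p in (self.gain_prob, self.loss_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def _instantiate(pattern: MotifPattern, rng: np.random.Generator) -> str:
    phi = sorted(PHI_ALPHABET)
    x = sorted(X_ALPHABET)
    out = []
    for sym in pattern.template:
        if sym == "P":
            out.append("P")
        elif sym == "phi":
            out.append(phi[rng.integers(len(phi))])
        else:
            out.append(x[rng.integers(len(x))])
    return "".join(out)


def generate_sequences(
    spec: SequenceSimSpec,
) -> tuple[list[SequenceRecord], list[MotifMatch], list[SecondaryStructureTrack]]:
    """Generate sequences, the planted-motif ground truth, and SS tracks.

    Plants are placed without overlap (left to right for ``nterm``, at the
    tail for ``cterm``, rejection-sampled for ``uniform``); the returned
    ground truth lists every planted span with its realized proline count.
    """
    rng = np.random.default_rng(spec.seed)
    alphabet = _AA20.replace("P", "") if spec.exclude_proline_background else _AA20
    records: list[SequenceRecord] = []
    truth: list[MotifMatch] = []
    tracks: list[SecondaryStructureTrack] = []
    lo, hi = spec.length_range
    for i in range(spec.n_proteins):
        n = int(rng.integers(lo, hi + 1))
        seq = list(alphabet[j] for j in rng.integers(len(alphabet), size=n))
        pid = f"sim{i:04d}"
        occupied: list[tuple[int, int]] = []  # 0-based half-open
        for name, policy in spec.planted:
            pat = PATTERNS[name]
            span = _instantiate(pat, rng)
            k = len(span)
            if policy == "nterm":
                pos = 0
                while any(pos < e and pos + k > s for s, e in occupied):
                    pos += 1
            elif policy == "cterm":
                pos = n - k
                while any(pos < e and pos + k > s for s, e in occupied) and pos > 0:
                    pos -= 1
            else:
                for _ in range(200):
                    pos = int(rng.integers(0, n - k + 1))
                    if not any(pos < e and pos + k > s for s, e in occupied):
                        break
            if pos < 0 or pos + k > n:
                raise ValueError("sequence too short for requested plants")
            seq[pos : pos + k] = span
            occupied.append((pos, pos + k))
            truth.append(
                MotifMatch(
                    protein_id=pid,
                    pattern=name,
                    start=pos + 1,
                    end=pos + k,
                    matched_span=span,
                    proline_count=span.count("P"),
                )
            )
        residues = "".join(seq)
        ss = ["C"] * n
        if spec.plant_anchr is not None and spec.plant_anchr:
            run_start, run_len = 2, 12  # helix inside the N-terminal window
            for j in range(run_start, min(run_start + run_len, n)):
                ss[j] = "H"
            if spec.anchr_with_proline:
                mid = run_start + run_len // 2
                seq[mid] = "P"
                residues = "".join(seq)
            else:
                # helix span must stay proline-free to emulate CdvBa1
                for j in range(run_start, min(run_start + run_len, n)):
                    if seq[j] == "P":
                        seq[j] = "L"
                residues = "".join(seq)
        records.append(SequenceRecord(id=pid, residues=residues))
        tracks.append(SecondaryStructureTrack(protein_id=pid, ss="".join(ss)))
    return records, truth, tracks


def simulate_domain_evolution(spec: EvolSimSpec) -> list[PresenceMatrix]:
    """Evolve binary characters root→leaves; one PresenceMatrix per replicate.

    On each branch a present character is lost with ``loss_prob`` and an
    absent one gained with ``gain_prob``, independently per character.
    """
    rng = np.random.default_rng(spec.seed)
    tree = spec.tree
    leaves = tree.leaf_labels()
    out: list[PresenceMatrix] = []
    for _ in range(spec.n_replicates):
        states: dict[str, np.ndarray] = {
            tree.root.label: np.array(spec.root_states, dtype=np.int8)
        }
        for parent, child in tree.branches():
            cur = states[parent.label].copy()
            u = rng.random(len(cur))
            lose = (cur == 1) & (u < spec.loss_prob)
            gain = (cur == 0) & (u < spec.gain_prob)
            cur[lose] = 0
            cur[gain] = 1
            states[child.label] = cur
        out.append(
            PresenceMatrix(
                taxa=list(leaves),
                characters=list(spec.characters),
                states=[states[leaf].tolist() for leaf in leaves],
            )
        )
    return out


def _prot(
    pid: str,
    family: Family,
    phylum: SuperPhylum,
    domains: list[tuple[DomainType, int, int]],
    mim2_prolines: Optional[int] = None,
) -> ProteinArchitecture:
    insts = []
    for dtype, start, end in domains:
        pc = mim2_prolines if dtype is DomainType.MIM2 else None
        insts.append(
            DomainInstance(dtype, start, end, Evidence.DB_SCAN, proline_count=pc)
        )
    return ProteinArchitecture(
        protein_id=pid, family=family, super_phylum=phylum, domains=insts
    )


def make_paper_protein_sets() -> dict[str, list[ProteinArchitecture]]:
    """The ancestral protein sets of the three phylogenetic groups.

    Crenarchaeota: CdvA (CdvA_alpha, CdvA_beta, BWI), CdvB (Snf7, MIM2, BWH),
    CdvB1/2 (Snf7, MIM2), CdvB3 (Snf7), CdvC (MIT, AAA_ATPase, Vps4_C).
    Thaumarchaeota: CdvA carries MIM2 instead of BWI and there is a single
    CdvB (Snf7, MIM2). Asgard: no CdvA; CdvBa1 (ANCHR, Snf7, MIM1) and
    CdvBa2 (Snf7, MIM2) plus CdvC. CdvB-class MIM2 instances carry 4
    prolines, CdvB1/2-class instances 2 — the affinity-relevant difference.
    """
    D = DomainType
    cren = [
        _prot("CdvA", Family.CDVA, SuperPhylum.TACK_CRENARCHAEOTA,
              [(D.CDVA_ALPHA, 12, 150), (D.CDVA_BETA, 158, 232), (D.BWI, 240, 252)]),
        _prot("CdvB", Family.CDVB, SuperPhylum.TACK_CRENARCHAEOTA,
              [(D.SNF7, 10, 170), (D.BWH, 178, 206), (D.MIM2, 215, 224)],
              mim2_prolines=4),
        _prot("CdvB1/2", Family.CDVB, SuperPhylum.TACK_CRENARCHAEOTA,
              [(D.SNF7, 10, 168), (D.MIM2, 198, 207)], mim2_prolines=2),
        _prot("CdvB3", Family.CDVB, SuperPhylum.TACK_CRENARCHAEOTA,
              [(D.SNF7, 12, 172)]),
        _prot("CdvC", Family.CDVC, SuperPhylum.TACK_CRENARCHAEOTA,
              [(D.MIT, 5, 80), (D.AAA_ATPASE, 95, 300), (D.VPS4_C, 310, 365)]),
    ]
    thaum = [
        _prot("CdvA", Family.CDVA, SuperPhylum.TACK_THAUMARCHAEOTA,
              [(D.CDVA_ALPHA, 12, 150), (D.CDVA_BETA, 158, 232), (D.MIM2, 240, 249)],
              mim2_prolines=4),
        _prot("CdvB", Family.CDVB, SuperPhylum.TACK_THAUMARCHAEOTA,
              [(D.SNF7, 10, 168), (D.MIM2, 200, 209)], mim2_prolines=4),
        _prot("CdvC", Family.CDVC, SuperPhylum.TACK_THAUMARCHAEOTA,
              [(D.MIT, 5, 80), (D.AAA_ATPASE, 95, 300), (D.VPS4_C, 310, 365)]),
    ]
    asgard = [
        _prot("CdvBa1", Family.CDVB, SuperPhylum.ASGARD,
              [(D.ANCHR, 2, 24), (D.SNF7, 30, 190), (D.MIM1, 230, 248)]),
        _prot("CdvBa2", Family.CDVB, SuperPhylum.ASGARD,
              [(D.SNF7, 30, 188), (D.MIM2, 220, 229)], mim2_prolines=4),
        _prot("CdvC", Family.CDVC, SuperPhylum.ASGARD,
              [(D.MIT, 5, 78), (D.AAA_ATPASE, 92, 298), (D.VPS4_C, 308, 362)]),
    ]
    return {"Crenarchaeota": cren, "Thaumarchaeota": thaum, "Asgard": asgard}
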