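"""Short-linear-motif detection on Cdv protein sequences.

Three MIT-interacting-motif-2 (MIM2) variants are defined over two residue
classes: the hydrophobic class φ = {A,I,L,M,F,V,P,G,W} and the charged class
x = {R,K,D,E} (P is always literal proline):

* ``MIM2_Core``  = φPxφP                      (length 5, 2 guaranteed P)
* ``MIM2_total`` = φPxφP followed by xxPφP    (length 10, 4 guaranteed P)
* ``MIM2_Sulf``  = xφxxφφPx followed by φPxφP (length 13, 3 guaranteed P)

Composite templates are immediate concatenations (no gap), matching the
proline spacing of the aligned motifs. Unknown residues (X) belong to neither
class, so they never satisfy a φ or x position. All matches at all offsets
are reported; overlap resolution is left to downstream consumers.

Beyond the exact regexes, two softer calls are provided: ``putative MIM2``
(a proline-rich C-terminal window in proteins without a full match — the
thresholds are this package's own, config-exposed defaults) and the ANCHR
membrane-binding helix call (an N-terminal predicted helix uninterrupted by
proline; a helix-breaking proline vetoes the call).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional

from .types import Evidence, HelixCall, MotifMatch, SecondaryStructureTrack, SequenceRecord

__all__ = [
    "PHI_ALPHABET",
    "X_ALPHABET",
    "MotifPattern",
    "PATTERNS",
    "scan_mim2",
    "min_guaranteed_prolines",
    "detect_putative_mim2",
    "call_anchr",
]

PHI_ALPHABET = frozenset("AILMFVPGW")
X_ALPHABET = frozenset("RKDE")

_CLASS_REGEX = {
    "phi": "[" + "".join(sorted(PHI_ALPHABET)) + "]",
    "x": "[" + "".join(sorted(X_ALPHABET)) + "]",
    "P": "P",
}


@dataclass(frozen=True)
class MotifPattern:
    """A motif template as an ordered tuple of position classes."""

    name: str
    template: tuple[str, ...]  # each element one of "phi", "x", "P"

    def __post_init__(self) -> None:
        bad = set(self.template) - set(_CLASS_REGEX)
        if bad:
            raise ValueError(f"unknown template symbols {bad}")

    def __len__(self) -> int:
        return len(self.template)

    @property
    def regex(self) -> str:
        return "".join(_CLASS_REGEX[sym] for sym in self.template)


_CORE = ("phi", "P", "x", "phi", "P")
_TOTAL_SUFFIX = ("x", "x", "P", "phi", "P")
_SULF_PREFIX = ("x", "phi", "x", "x", "phi", "phi", "P", "x")

PATTERNS: dict[str, MotifPattern] = {
    "MIM2_Core": MotifPattern("MIM2_Core", _CORE),
    "MIM2_total": MotifPattern("MIM2_total", _CORE + _TOTAL_SUFFIX),
    "MIM2_Sulf": MotifPattern("MIM2_Sulf", _SULF_PREFIX + _CORE),
}


def min_guaranteed_prolines(pattern: MotifPattern | str) -> int:
    """Number of literal P positions in a template (lower bound on any match)."""
    if isinstance(pattern, str):
        try:
            pattern = PATTERNS[pattern]
        except KeyError:
            raise KeyError(
                f"unknown pattern {pattern!r}; known: {sorted(PATTERNS)}"
            ) from None
    return sum(1 for sym in pattern.template if sym == "P")


def scan_mim2(
    record: SequenceRecord,
    patterns: Optional[Iterable[MotifPattern | str]] = None,
) -> list[MotifMatch]:
    """Find all (possibly overlapping) matches of the requested MIM2 variants.

    Matches are reported with 1-based inclusive coordinates and the proline
    count of the matched span. An empty sequence yields an empty list.
    """
    if patterns is None:
        pats = list(PATTERNS.values())
    else:
        pats = [PATTERNS[p] if isinstance(p, str) else p for p in patterns]
    seq = record.residues
    out: list[MotifMatch] = []
    for pat in pats:
        # lookahead capture -> overlapping matches included
        for m in re.finditer(f"(?=({pat.regex}))", seq):
            span = m.group(1)
            start = m.start() + 1
            out.append(
                MotifMatch(
                    protein_id=record.id,
                    pattern=pat.name,
                    start=start,
                    end=start + len(pat) - 1,
                    matched_span=span,
                    proline_count=span.count("P"),
                )
            )
    out.sort(key=lambda mm: (mm.start, mm.end, mm.pattern))
    return out


def detect_putative_mim2(
    record: SequenceRecord,
    window: int = 15,
    min_prolines: int = 3,
    cterm_fraction: float = 0.5,
) -> list[MotifMatch]:
    """Call proline-rich C-terminal regions as putative MIM2.

    A window of ``window`` residues lying in the C-terminal ``cterm_fraction``
    of the sequence qualifies when it contains at least ``min_prolines``
    prolines; overlapping qualifying windows are merged into maximal spans.
    A protein with any full MIM2 match receives no putative call (the exact
    motif takes precedence). Thresholds are package defaults, config-exposed.
    """
    if window < 5:
        raise ValueError("window must be >= 5")
    seq = record.residues
    n = len(seq)
    if n < window:
        return []
    if scan_mim2(record):
        return []
    region_start0 = int(n * (1.0 - cterm_fraction))  # 0-based
    hits: list[tuple[int, int]] = []  # 0-based half-open
    for i in range(region_start0, n - window + 1):
        if seq[i : i + window].count("P") >= min_prolines:
            hits.append((i, i + window))
    if not hits:
        return []
    merged: list[list[int]] = [list(hits[0])]
    for s, e in hits[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [
        MotifMatch(
            protein_id=record.id,
            pattern="putative_MIM2",
            start=s + 1,
            end=e,
            matched_span=seq[s:e],
            proline_count=seq[s:e].count("P"),
            evidence=Evidence.PUTATIVE,
        )
        for s, e in merged
    ]


def call_anchr(
    record: SequenceRecord,
    ss: SecondaryStructureTrack,
    nterm_len: int = 30,
    min_helix_run: int = 8,
) -> HelixCall:
    """Decide whether the N-terminus carries an ANCHR-like membrane helix.

    The first ``nterm_len`` residues are examined; the call is positive when
    the longest predicted helix run there reaches ``min_helix_run`` residues
    and contains no proline (a helix-breaking proline vetoes membrane
    binding). With no helix run at all, prolines anywhere in the window are
    reported instead.
    """
    if len(ss.ss) != len(record.residues):
        raise ValueError(
            f"{record.id}: secondary-structure length {len(ss.ss)} != "
            f"sequence length {len(record.residues)}"
        )
    n = min(nterm_len, len(record.residues))
    window_ss = ss.ss[:n]
    window_seq = record.residues[:n]

    best: tuple[int, int] | None = None  # (start0, length), first maximal run
    run_start = None
    for i, ch in enumerate(window_ss + "."):
        if ch == "H":
            if run_start is None:
                run_start = i
        elif run_start is not None:
            length = i - run_start
            if best is None or length > best[1]:
                best = (run_start, length)
            run_start = None

    if best is None:
        return HelixCall(
            protein_id=record.id,
            region_start=1,
            region_end=n,
            is_helix=False,
            has_proline="P" in window_seq,
        )
    start0, length = best
    run_seq = window_seq[start0 : start0 + length]
    return HelixCall(
        protein_id=record.id,
        region_start=start0 + 1,
        region_end=start0 + length,
        is_helix=length >= min_helix_run,
        has_proline="P" in run_seq,
    )
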