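"""Domain-rule-based PPI networks and qualitative mechanism inference.

Interactions between Cdv proteins are modelled entirely through unordered
domain-type pairs. The default rule set holds the experimentally supported
pairs (MIM2-MIT and BWI-BWH binding; Snf7-Snf7 and Vps4_C-Vps4_C
polymerization) plus two rules with weaker support kept at ``putative``
status (CdvA_beta self-polymerization, MIM1-MIT binding). A protein carrying
both MIT and AAA+ ATPase acts as a disassembler: once it has bound a partner
family, polymerized members of that family reachable through an enabled
MIM-MIT rule are depolymerized.

Mechanism inference replays the recruitment logic qualitatively: start from
the unique membrane-binding protein, repeatedly fire the highest-affinity
available interaction, and fork into separate scenarios only where the rule
set leaves genuinely incomparable options (putative routes, or re-use of an
already-engaged domain, e.g. a disassembler's MIT moonlighting as a linker).
No kinetics are simulated; the affinity order is a fixed qualitative ranking.
"""

from __future__ import annotations

import copy
import itertools
import json
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence, Union

import networkx as nx

from .types import DomainType, Family, ProteinArchitecture

__all__ = [
    "RuleStatus",
    "RuleEffect",
    "InteractionRule",
    "InteractionRuleSet",
    "default_rules",
    "PPIEdge",
    "PPINetwork",
    "build_ppi",
    "Candidate",
    "rank_affinity",
    "MechanismEvent",
    "MechanismScenario",
    "infer_mechanism",
]


class RuleStatus(str, Enum):
    VALIDATED = "validated"
    PUTATIVE = "putative"
    DISABLED = "disabled"


class RuleEffect(str, Enum):
    BINDING = "binding"
    POLYMERIZATION = "polymerization"


@dataclass(frozen=True)
class InteractionRule:
    pair: frozenset[DomainType]  # one element = homotypic self-interaction
    status: RuleStatus
    effect: RuleEffect

    def __post_init__(self) -> None:
        if not 1 <= len(self.pair) <= 2:
            raise ValueError("rule pair must contain one or two domain types")

    @property
    def sorted_pair(self) -> tuple[DomainType, ...]:
        return tuple(sorted(self.pair, key=lambda d: d.value))


class InteractionRuleSet:
    def __init__(self, rules: Iterable[InteractionRule]):
        self.rules = list(rules)
        if not self.rules:
            raise ValueError("rule set must not be empty")

    def enabled(self) -> list[InteractionRule]:
        return [r for r in self.rules if r.status is not RuleStatus.DISABLED]

    def with_status(
        self, pair: Iterable[DomainType], status: RuleStatus
    ) -> "InteractionRuleSet":
        """Return a copy with the rule for ``pair`` set to ``status``."""
        target = frozenset(pair)
        out = []
        found = False
        for r in self.rules:
            if r.pair == target:
                out.append(InteractionRule(r.pair, status, r.effect))
                found = True
            else:
                out.append(r)
        if not found:
            raise KeyError(f"no rule for pair {sorted(d.value for d in target)}")
        return InteractionRuleSet(out)

    @classmethod
    def from_json(cls, text: str) -> "InteractionRuleSet":
        data = json.loads(text)
        return cls(
            InteractionRule(
                pair=frozenset(DomainType(d) for d in entry["domains"]),
                status=RuleStatus(entry["status"]),
                effect=RuleEffect(entry["effect"]),
            )
            for entry in data
        )

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "domains": [d.value for d in r.sorted_pair],
                    "status": r.status.value,
                    "effect": r.effect.value,
                }
                for r in self.rules
            ],
            indent=2,
        )


def default_rules() -> InteractionRuleSet:
    """The literature-derived domain-interaction rule table."""
    return InteractionRuleSet(
        [
            InteractionRule(
                frozenset({DomainType.MIM2, DomainType.MIT}),
                RuleStatus.VALIDATED, RuleEffect.BINDING,
            ),
            InteractionRule(
                frozenset({DomainType.BWI, DomainType.BWH}),
                RuleStatus.VALIDATED, RuleEffect.BINDING,
            ),
            InteractionRule(
                frozenset({DomainType.SNF7}),
                RuleStatus.VALIDATED, RuleEffect.POLYMERIZATION,
            ),
            InteractionRule(
                frozenset({DomainType.VPS4_C}),
                RuleStatus.VALIDATED, RuleEffect.POLYMERIZATION,
            ),
            InteractionRule(
                frozenset({DomainType.CDVA_BETA}),
                RuleStatus.PUTATIVE, RuleEffect.POLYMERIZATION,
            ),
            InteractionRule(
                frozenset({DomainType.MIM1, DomainType.MIT}),
                RuleStatus.PUTATIVE, RuleEffect.BINDING,
            ),
        ]
    )


# ---------------------------------------------------------------------------
# PPI networks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PPIEdge:
    node_a: str
    node_b: str
    domain_pair: tuple[str, ...]
    status: RuleStatus
    effect: RuleEffect


@dataclass
class PPINetwork:
    graph: nx.MultiGraph
    qualitative: bool

    @property
    def edges(self) -> list[PPIEdge]:
        out = []
        for u, v, data in self.graph.edges(data=True):
            a, b = sorted((u, v))
            out.append(
                PPIEdge(a, b, data["domain_pair"], data["status"], data["effect"])
            )
        return sorted(out, key=lambda e: (e.node_a, e.node_b, e.domain_pair))

    def count_validated(self) -> int:
        return sum(1 for e in self.edges if e.status is RuleStatus.VALIDATED)


def _family_label(protein: ProteinArchitecture) -> str:
    return protein.family.value


def build_ppi(
    proteins: Sequence[ProteinArchitecture],
    rules: Optional[InteractionRuleSet] = None,
    qualitative: bool = False,
) -> PPINetwork:
    """Build the domain-justified PPI (multi)graph over proteins or families.

    An edge (possibly a self-loop, for polymerization) is added for every
    enabled rule whose two domain types are carried by the two endpoints.
    In qualitative mode proteins are first collapsed onto family labels
    (paralogs merge into one node whose domain set is the union) and
    duplicate (node-pair, domain-pair) edges are dropped — the family-level
    view used to compare machineries between phylogenetic groups.
    """
    rules = rules or default_rules()
    if qualitative:
        nodes: dict[str, set[DomainType]] = {}
        for p in proteins:
            nodes.setdefault(_family_label(p), set()).update(p.domain_types)
    else:
        nodes = {p.protein_id: set(p.domain_types) for p in proteins}

    graph = nx.MultiGraph()
    graph.add_nodes_from(sorted(nodes))
    seen: set[tuple] = set()
    for rule in rules.enabled():
        pair = rule.sorted_pair
        for u, v in itertools.combinations_with_replacement(sorted(nodes), 2):
            du, dv = set(nodes[u]), set(nodes[v])
            if len(pair) == 1:
                ok = pair[0] in du and pair[0] in dv
            else:
                d1, d2 = pair
                ok = (d1 in du and d2 in dv) or (d2 in du and d1 in dv)
            if not ok:
                continue
            if rule.effect is RuleEffect.POLYMERIZATION and u != v:
                # polymerization is homotypic; distinct-node edges are kept
                # only in protein-level mode (paralog-paralog filaments)
                if qualitative:
                    continue
            key = (u, v, tuple(d.value for d in pair))
            if qualitative and key in seen:
                continue
            seen.add(key)
            graph.add_edge(
                u, v,
                domain_pair=tuple(d.value for d in pair),
                status=rule.status,
                effect=rule.effect,
            )
    return PPINetwork(graph=graph, qualitative=qualitative)


# ---------------------------------------------------------------------------
# Affinity ranking
# ---------------------------------------------------------------------------

# Qualitative affinity tiers: membrane binding strongest, then the tether
# (BWI-BWH), filament formation (Snf7), MIM-MIT recruitment (proline count of
# the MIM2 instance breaks ties; MIM1 ranks as zero prolines), Vps4_C
# hexamerization; unranked rules (putative polymerizations) come last.
_TIER_MEMBRANE = 0
_TIERS: dict[frozenset[DomainType], int] = {
    frozenset({DomainType.BWI, DomainType.BWH}): 1,
    frozenset({DomainType.SNF7}): 2,
    frozenset({DomainType.MIM2, DomainType.MIT}): 3,
    frozenset({DomainType.MIM1, DomainType.MIT}): 3,
    frozenset({DomainType.VPS4_C}): 4,
}
_TIER_UNRANKED = 5


@dataclass(frozen=True)
class Candidate:
    """One possible next interaction in a mechanism state."""

    kind: str  # membrane_bind | recruit | bind | polymerize
    actor: str
    target: Union[str, tuple[str, ...], None]
    domain_pair: tuple[str, ...]
    rule_pair: frozenset[DomainType]
    questionable: bool = False
    proline_count: int = 0

    @property
    def key(self) -> tuple:
        tgt = self.target if isinstance(self.target, (str, type(None))) else tuple(self.target)
        return (self.kind, self.actor, tgt, self.domain_pair)

    def tier(self) -> int:
        if self.kind == "membrane_bind":
            return _TIER_MEMBRANE
        return _TIERS.get(self.rule_pair, _TIER_UNRANKED)


def rank_affinity(candidates: Iterable[Candidate]) -> list[Candidate]:
    """Order candidate interactions by the qualitative affinity ranking.

    Total order: membrane binding > BWI-BWH > Snf7-Snf7 > MIM-MIT (descending
    proline count of the partner's MIM2; MIM1 counts as zero) > Vps4_C-Vps4_C
    > unranked rules; remaining ties break lexicographically on the protein
    labels, so the ordering is deterministic.
    """
    def sort_key(c: Candidate):
        tgt = c.target if isinstance(c.target, str) else (
            ",".join(c.target) if c.target else ""
        )
        return (c.tier(), -c.proline_count, c.actor, tgt, c.domain_pair)

    return sorted(candidates, key=sort_key)


# ---------------------------------------------------------------------------
# Mechanism inference
# ---------------------------------------------------------------------------

MEMBRANE_BINDING_DOMAINS = {DomainType.CDVA_ALPHA, DomainType.ANCHR}


@dataclass(frozen=True)
class MechanismEvent:
    step_index: int
    kind: str  # membrane_bind | recruit | polymerize | bind | disassemble
    actor: str
    target: Union[str, tuple[str, ...], None]
    domain_pair: tuple[str, ...]


@dataclass
class MechanismScenario:
    branch_id: str
    events: list[MechanismEvent]
    unresolved: frozenset[str]

    def event_kinds(self) -> list[str]:
        return [e.kind for e in self.events]


def _is_disassembler(p: ProteinArchitecture) -> bool:
    return p.has(DomainType.MIT, DomainType.AAA_ATPASE)


def _mim_partner_domains(rules: InteractionRuleSet) -> list[tuple[DomainType, frozenset]]:
    """Enabled domains that pair with MIT (the disassembly receptors)."""
    out = []
    for r in rules.enabled():
        if r.effect is RuleEffect.BINDING and DomainType.MIT in r.pair and len(r.pair) == 2:
            (other,) = r.pair - {DomainType.MIT}
            out.append((other, r.pair))
    return out


class _State:
    """Mutable per-scenario bookkeeping for the mechanism engine."""

    def __init__(self) -> None:
        self.events: list[MechanismEvent] = []
        self.present: dict[str, str] = {}  # pid -> "scaffold" | "bound"
        self.engaged: dict[tuple[str, str], int] = {}  # (pid, domain) -> uses
        self.polymerized: set[str] = set()
        self.poly_done: set[tuple[str, str]] = set()
        self.links: set[frozenset[str]] = set()  # protein-pair links made
        self.bound_families: dict[str, set[Family]] = {}  # disassembler -> families
        self.compromised: set[str] = set()  # linker-compromised disassemblers
        self.disabled: set[tuple] = set()  # forked-away candidate keys
        self.disassembled: set[str] = set()
        self.path: list[int] = []

    def clone(self) -> "_State":
        return copy.deepcopy(self)

    def free(self, pid: str, domain: DomainType, capacity: dict) -> bool:
        return self.engaged.get((pid, domain.value), 0) < capacity[(pid, domain.value)]

    def engage(self, pid: str, domain: DomainType) -> None:
        key = (pid, domain.value)
        self.engaged[key] = self.engaged.get(key, 0) + 1

    def emit(self, kind: str, actor: str, target, domain_pair: tuple[str, ...]) -> None:
        self.events.append(
            MechanismEvent(len(self.events), kind, actor, target, domain_pair)
        )


def _enumerate_candidates(
    state: _State,
    proteins: dict[str, ProteinArchitecture],
    rules: InteractionRuleSet,
    capacity: dict,
) -> list[Candidate]:
    cands: list[Candidate] = []
    for rule in rules.enabled():
        putative = rule.status is RuleStatus.PUTATIVE
        if rule.effect is RuleEffect.POLYMERIZATION:
            (dom,) = rule.pair if len(rule.pair) == 1 else (None,)
            if dom is None:
                continue
            for pid, mode in state.present.items():
                if mode != "scaffold" or (pid, dom.value) in state.poly_done:
                    continue
                if dom not in proteins[pid].domain_types:
                    continue
                targets = tuple(
                    sorted(
                        q for q, qp in proteins.items()
                        if q != pid and q not in state.present
                        and dom in qp.domain_types
                    )
                )
                cands.append(
                    Candidate(
                        kind="polymerize", actor=pid, target=targets,
                        domain_pair=(dom.value,), rule_pair=rule.pair,
                        questionable=putative,
                    )
                )
        else:  # binding
            if len(rule.pair) != 2:
                continue
            d1, d2 = tuple(rule.pair)
            for a, b in itertools.permutations(sorted(proteins), 2):
                if a not in state.present:
                    continue  # at least one endpoint must already be present
                pa, pb = proteins[a], proteins[b]
                if d1 in pa.domain_types and d2 in pb.domain_types:
                    da, db = d1, d2
                elif d2 in pa.domain_types and d1 in pb.domain_types:
                    da, db = d2, d1
                else:
                    continue
                if frozenset({a, b}) in state.links:
                    continue
                reuse = not state.free(a, da, capacity) or not state.free(b, db, capacity)
                questionable = putative or reuse
                if _is_disassembler(pb):
                    kind, actor, target = "bind", b, a
                elif _is_disassembler(pa):
                    kind, actor, target = "bind", a, b
                elif b not in state.present:
                    kind, actor, target = "recruit", b, a
                else:
                    kind, actor, target = "bind", min(a, b), max(a, b)
                mim_pc = 0
                for side, dom in ((pa, da), (pb, db)):
                    if dom in (DomainType.MIM2, DomainType.MIM1):
                        inst = side.instance(dom)
                        if dom is DomainType.MIM2 and inst is not None:
                            mim_pc = inst.proline_count or 0
                cands.append(
                    Candidate(
                        kind=kind, actor=actor, target=target,
                        domain_pair=tuple(sorted((da.value, db.value))),
                        rule_pair=rule.pair,
                        questionable=questionable, proline_count=mim_pc,
                    )
                )
    # drop duplicates (two orientations can describe the same interaction)
    uniq: dict[tuple, Candidate] = {}
    for c in rank_affinity(cands):
        if c.key not in state.disabled and c.key not in uniq:
            uniq[c.key] = c
    return list(uniq.values())


def _fire(
    state: _State,
    cand: Candidate,
    proteins: dict[str, ProteinArchitecture],
) -> None:
    if cand.kind == "polymerize":
        state.emit("polymerize", cand.actor, cand.target, cand.domain_pair)
        state.polymerized.add(cand.actor)
        state.poly_done.add((cand.actor, cand.domain_pair[0]))
        for pid in cand.target or ():
            state.present[pid] = "scaffold"
            state.polymerized.add(pid)
            state.poly_done.add((pid, cand.domain_pair[0]))
        return
    # binding / recruiting
    a, b = cand.actor, cand.target
    assert isinstance(b, str)
    d1, d2 = (DomainType(x) for x in cand.domain_pair)
    if d1 in proteins[a].domain_types and d2 in proteins[b].domain_types:
        engagements = [(a, d1), (b, d2)]
    else:
        engagements = [(a, d2), (b, d1)]
    for pid, dom in engagements:  # one slot per side; overuse marks a linker
        state.engage(pid, dom)
    state.links.add(frozenset({a, b}))
    newly_present = [p for p in (a, b) if p not in state.present]
    if cand.kind == "recruit":
        for pid in newly_present:
            state.present[pid] = "scaffold"
        state.emit("recruit", a, b, cand.domain_pair)
        return
    # bind
    disassembler = a if _is_disassembler(proteins[a]) else (
        b if _is_disassembler(proteins[b]) else None
    )
    for pid in newly_present:
        if disassembler is not None and pid == disassembler:
            state.present[pid] = "bound"
        else:
            state.present[pid] = "scaffold"
    state.emit("bind", a, b, cand.domain_pair)
    if disassembler is not None:
        partner = b if disassembler == a else a
        state.bound_families.setdefault(disassembler, set()).add(
            proteins[partner].family
        )
        # a disassembler whose binding domain was already engaged is acting
        # as a linker and loses its depolymerization capability
        over = any(
            state.engaged.get((disassembler, d.value), 0) > 1
            for d in proteins[disassembler].domain_types
            if d is DomainType.MIT
        )
        if over:
            state.compromised.add(disassembler)


def _try_cascade(
    state: _State,
    proteins: dict[str, ProteinArchitecture],
    rules: InteractionRuleSet,
) -> bool:
    """Fire the depolymerization cascade if a competent disassembler is bound.

    Returns True when disassembly happened (the scenario then terminates).
    """
    receptors = _mim_partner_domains(rules)
    for dis in sorted(state.bound_families):
        if dis in state.compromised or dis not in state.present:
            continue
        families = state.bound_families[dis]
        targets: list[tuple[int, str, tuple[str, ...]]] = []
        for pid in sorted(state.polymerized - state.disassembled):
            prot = proteins[pid]
            if prot.family not in families:
                continue
            for mim_dom, pair in receptors:
                if mim_dom in prot.domain_types:
                    inst = prot.instance(mim_dom)
                    pc = (inst.proline_count or 0) if (
                        inst is not None and mim_dom is DomainType.MIM2
                    ) else 0
                    targets.append(
                        (pc, pid, tuple(sorted(d.value for d in pair)))
                    )
                    break
        if not targets:
            continue
        for pc, pid, pair in sorted(targets, key=lambda t: (-t[0], t[1])):
            state.emit("disassemble", dis, pid, pair)
            state.disassembled.add(pid)
        return True
    return False


def infer_mechanism(
    proteins: Sequence[ProteinArchitecture],
    rules: Optional[InteractionRuleSet] = None,
    start: str = "auto",
    max_branches: int = 8,
) -> list[MechanismScenario]:
    """Infer qualitative assembly/disassembly scenarios for a protein set.

    The expansion is depth-first and deterministic: while an unambiguous
    (validated, capacity-respecting) interaction exists, the highest-affinity
    one fires; when only questionable options remain and no disassembly has
    happened yet, one scenario is forked per option (alternatives are
    disabled within each sibling branch); a depolymerization cascade ends a
    scenario. Proteins that polymerized but could never be disassembled are
    reported as unresolved.
    """
    rules = rules or default_rules()
    prot_map = {p.protein_id: p for p in proteins}
    if len(prot_map) != len(proteins):
        raise ValueError("protein labels must be unique")
    capacity = {
        (p.protein_id, d.domain_type.value): sum(
            1 for x in p.domains if x.domain_type is d.domain_type
        )
        for p in proteins
        for d in p.domains
    }

    if start == "auto":
        starters = sorted(
            p.protein_id
            for p in proteins
            if p.domain_types & MEMBRANE_BINDING_DOMAINS
        )
        if len(starters) != 1:
            raise ValueError(
                "start='auto' needs exactly one membrane-binding protein "
                f"(found {starters or 'none'}); pass start= explicitly"
            )
        start = starters[0]
    elif start not in prot_map:
        raise KeyError(f"unknown start protein {start!r}")

    membrane_dom = sorted(
        d.value for d in prot_map[start].domain_types & MEMBRANE_BINDING_DOMAINS
    )
    init = _State()
    init.present[start] = "scaffold"
    init.emit("membrane_bind", start, "membrane", tuple(membrane_dom))

    scenarios: list[MechanismScenario] = []
    stack: list[_State] = [init]
    n_branches = 1
    while stack:
        state = stack.pop()
        finished = False
        while not finished:
            if _try_cascade(state, prot_map, rules):
                finished = True
                break
            cands = _enumerate_candidates(state, prot_map, rules, capacity)
            clean = [c for c in cands if not c.questionable]
            if clean:
                _fire(state, rank_affinity(clean)[0], prot_map)
                continue
            if cands:
                ordered = rank_affinity(cands)
                if len(ordered) > 1 and n_branches < max_branches:
                    take = ordered[: max_branches - n_branches + 1]
                    n_branches += len(take) - 1
                    for i, choice in reversed(list(enumerate(take))):
                        branch = state.clone() if i > 0 else state
                        branch.disabled |= {
                            c.key for j, c in enumerate(take) if j != i
                        }
                        branch.path.append(i)
                        _fire(branch, choice, prot_map)
                        if i > 0:
                            stack.append(branch)
                    continue
                _fire(state, ordered[0], prot_map)
                continue
            finished = True
        unresolved = frozenset(state.polymerized - state.disassembled)
        branch_id = "s" + ("." .join(str(i) for i in state.path) or "0")
        scenarios.append(MechanismScenario(branch_id, state.events, unresolved))
    scenarios.sort(key=lambda s: s.branch_id)
    return scenarios
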