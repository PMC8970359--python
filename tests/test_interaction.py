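import random

import pytest

from cdvkit import interaction as itx
from cdvkit.interaction import Candidate, RuleStatus
from cdvkit.types import (
    DomainInstance,
    DomainType,
    Evidence,
    Family,
    ProteinArchitecture,
    SuperPhylum,
)

D = DomainType


def _arch(pid, doms, family=Family.CDVB):
    return ProteinArchitecture(
        protein_id=pid, family=family,
        domains=[DomainInstance(d, 10 * (i + 1), 10 * (i + 1) + 5, Evidence.DB_SCAN)
                 for i, d in enumerate(doms)],
    )


class TestRuleSet:
    def test_default_rule_table(self):
        rules = itx.default_rules()
        by_pair = {r.pair: r for r in rules.rules}
        validated = {p for p, r in by_pair.items() if r.status is RuleStatus.VALIDATED}
        assert validated == {
            frozenset({D.MIM2, D.MIT}), frozenset({D.BWI, D.BWH}),
            frozenset({D.SNF7}), frozenset({D.VPS4_C}),
        }
        putative = {p for p, r in by_pair.items() if r.status is RuleStatus.PUTATIVE}
        assert putative == {frozenset({D.CDVA_BETA}), frozenset({D.MIM1, D.MIT})}

    def test_json_round_trip(self):
        rules = itx.default_rules()
        back = itx.InteractionRuleSet.from_json(rules.to_json())
        assert {(r.pair, r.status, r.effect) for r in back.rules} == {
            (r.pair, r.status, r.effect) for r in rules.rules
        }

    def test_with_status_unknown_pair_rejected(self):
        with pytest.raises(KeyError):
            itx.default_rules().with_status({D.BWI, D.MIM1}, RuleStatus.DISABLED)


class TestBuildPpi:
    def test_thaumarchaeota_qualitative_network(self, paper_sets):
        net = itx.build_ppi(paper_sets["Thaumarchaeota"], qualitative=True)
        validated = {
            (e.node_a, e.node_b, e.domain_pair)
            for e in net.edges if e.status is RuleStatus.VALIDATED
        }
        assert validated == {
            ("CdvA", "CdvC", ("MIM2", "MIT")),
            ("CdvB", "CdvC", ("MIM2", "MIT")),
            ("CdvB", "CdvB", ("Snf7",)),
            ("CdvC", "CdvC", ("Vps4_C",)),
        }
        assert net.count_validated() == 4

    def test_crenarchaeota_qualitative_network(self, paper_sets):
        net = itx.build_ppi(paper_sets["Crenarchaeota"], qualitative=True)
        validated = {
            (e.node_a, e.node_b, e.domain_pair)
            for e in net.edges if e.status is RuleStatus.VALIDATED
        }
        assert validated == {
            ("CdvA", "CdvB", ("BWH", "BWI")),
            ("CdvB", "CdvB", ("Snf7",)),
            ("CdvB", "CdvC", ("MIM2", "MIT")),
            ("CdvC", "CdvC", ("Vps4_C",)),
        }
        assert net.count_validated() == 4

    def test_putative_cdva_beta_loop_excluded_from_validated_count(self, paper_sets):
        net = itx.build_ppi(paper_sets["Thaumarchaeota"], qualitative=True)
        putative = [e for e in net.edges if e.status is RuleStatus.PUTATIVE]
        assert [(e.node_a, e.node_b, e.domain_pair) for e in putative] == [
            ("CdvA", "CdvA", ("CdvA_beta",))
        ]

    def test_empty_rule_effect(self, paper_sets):
        rules = itx.default_rules()
        for r in rules.rules:
            rules = rules.with_status(r.pair, RuleStatus.DISABLED)
        net = itx.build_ppi(paper_sets["Crenarchaeota"], rules, qualitative=True)
        assert net.edges == []

    def test_every_edge_justified_by_endpoint_domains(self):
        rng = random.Random(5)
        all_doms = list(D)
        for _ in range(30):
            prots = [
                _arch(f"p{i}", rng.sample(all_doms, rng.randint(1, 5)))
                for i in range(rng.randint(2, 6))
            ]
            net = itx.build_ppi(prots, qualitative=False)
            by_id = {p.protein_id: p.domain_types for p in prots}
            for e in net.edges:
                d1, d2 = e.domain_pair[0], e.domain_pair[-1]
                assert (
                    (D(d1) in by_id[e.node_a] and D(d2) in by_id[e.node_b])
                    or (D(d2) in by_id[e.node_a] and D(d1) in by_id[e.node_b])
                )

    def test_qualitative_count_invariant_under_paralog_duplication(self, paper_sets):
        cren = paper_sets["Crenarchaeota"]
        extra = _arch("CdvB1/2-dup", [D.SNF7, D.MIM2])
        net0 = itx.build_ppi(cren, qualitative=True)
        net1 = itx.build_ppi(list(cren) + [extra], qualitative=True)
        assert net0.count_validated() == net1.count_validated()


class TestRankAffinity:
    def _cand(self, pair, proline=0, actor="a", target="b"):
        return Candidate(
            kind="bind", actor=actor, target=target,
            domain_pair=tuple(sorted(d.value for d in pair)),
            rule_pair=frozenset(pair), proline_count=proline,
        )

    def test_snf7_before_mim2(self):
        snf7 = self._cand({D.SNF7})
        mim2 = self._cand({D.MIM2, D.MIT})
        assert itx.rank_affinity([mim2, snf7])[0] is snf7

    def test_proline_count_breaks_mim2_ties(self):
        strong = self._cand({D.MIM2, D.MIT}, proline=4, actor="x")
        weak = self._cand({D.MIM2, D.MIT}, proline=2, actor="a")
        assert itx.rank_affinity([weak, strong])[0] is strong

    def test_full_tier_order(self):
        order = [
            self._cand({D.BWI, D.BWH}),
            self._cand({D.SNF7}),
            self._cand({D.MIM2, D.MIT}, proline=2),
            self._cand({D.VPS4_C}),
            self._cand({D.CDVA_BETA}),
        ]
        shuffled = order[::-1]
        assert itx.rank_affinity(shuffled) == order

    def test_single_candidate_is_itself(self):
        c = self._cand({D.SNF7})
        assert itx.rank_affinity([c]) == [c]


class TestMechanism:
    def test_crenarchaeota_single_scenario_event_order(self, paper_sets):
        (scen,) = itx.infer_mechanism(paper_sets["Crenarchaeota"])
        assert [(e.kind, e.actor, e.target) for e in scen.events] == [
            ("membrane_bind", "CdvA", "membrane"),
            ("recruit", "CdvB", "CdvA"),
            ("polymerize", "CdvB", ("CdvB1/2", "CdvB3")),
            ("bind", "CdvC", "CdvB"),
            ("disassemble", "CdvC", "CdvB"),
            ("disassemble", "CdvC", "CdvB1/2"),
        ]
        assert scen.unresolved == {"CdvB3"}

    def test_cdvb_disassembled_before_cdvb12(self, paper_sets):
        (scen,) = itx.infer_mechanism(paper_sets["Crenarchaeota"])
        order = [e.target for e in scen.events if e.kind == "disassemble"]
        assert order.index("CdvB") < order.index("CdvB1/2")

    def test_thaumarchaeota_two_scenarios(self, paper_sets):
        scens = itx.infer_mechanism(paper_sets["Thaumarchaeota"])
        assert len(scens) == 2
        # one scenario disassembles the CdvA ring, the other leaves CdvB stuck
        summaries = {
            (("disassemble", "CdvA") in {(e.kind, e.target) for e in s.events},
             frozenset(s.unresolved))
            for s in scens
        }
        assert summaries == {(True, frozenset()), (False, frozenset({"CdvB"}))}

    def test_asgard_scenario_starts_at_cdvba1_and_resolves_all(self, paper_sets):
        (scen,) = itx.infer_mechanism(paper_sets["Asgard"])
        first = scen.events[0]
        assert (first.kind, first.actor) == ("membrane_bind", "CdvBa1")
        kinds = scen.event_kinds()
        assert "polymerize" in kinds and "disassemble" in kinds
        assert scen.unresolved == frozenset()

    def test_auto_start_requires_unique_membrane_binder(self, paper_sets):
        no_starter = [p for p in paper_sets["Asgard"] if p.protein_id != "CdvBa1"]
        with pytest.raises(ValueError, match="membrane-binding"):
            itx.infer_mechanism(no_starter)

    def test_deterministic_repeat_runs(self, paper_sets):
        for name in ("Crenarchaeota", "Thaumarchaeota", "Asgard"):
            a = itx.infer_mechanism(paper_sets[name])
            b = itx.infer_mechanism(paper_sets[name])
            assert [(s.branch_id, s.events, s.unresolved) for s in a] == [
                (s.branch_id, s.events, s.unresolved) for s in b
            ]

    def test_no_disabled_rule_is_ever_used(self, paper_sets):
        rules = itx.default_rules().with_status({D.MIM1, D.MIT}, RuleStatus.DISABLED)
        for name in ("Crenarchaeota", "Thaumarchaeota", "Asgard"):
            for scen in itx.infer_mechanism(paper_sets[name], rules):
                for e in scen.events:
                    assert set(e.domain_pair) != {"MIM1", "MIT"}

    def test_disabling_mim2_mit_removes_all_disassembly_in_tack(self, paper_sets):
        rules = itx.default_rules().with_status({D.MIM2, D.MIT}, RuleStatus.DISABLED)
        for name in ("Crenarchaeota", "Thaumarchaeota"):
            for scen in itx.infer_mechanism(paper_sets[name], rules):
                assert "disassemble" not in scen.event_kinds()

    def test_first_event_is_always_membrane_bind(self, paper_sets):
        for name, prots in paper_sets.items():
            for scen in itx.infer_mechanism(prots):
                assert scen.events[0].kind == "membrane_bind"

    def test_disassembly_preceded_by_family_bind(self, paper_sets):
        by_sets = {n: {p.protein_id: p for p in ps} for n, ps in paper_sets.items()}
        for name, prots in paper_sets.items():
            lookup = by_sets[name]
            for scen in itx.infer_mechanism(prots):
                bound_families = set()
                for e in scen.events:
                    if e.kind == "bind":
                        partner = e.target if isinstance(e.target, str) else None
                        if partner in lookup:
                            bound_families.add(lookup[partner].family)
                    if e.kind == "disassemble":
                        assert lookup[e.target].family in bound_families
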