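import random

import pandas as pd
import pytest

from cdvkit import architecture as arch
from cdvkit.architecture import ArchitectureClass
from cdvkit.types import (
    AnnotationRow,
    ArchitectureTable,
    DomainInstance,
    DomainType,
    Evidence,
    Family,
    MotifMatch,
    ProteinArchitecture,
    SuperPhylum,
)

D = DomainType


def _arch(pid, doms, family=Family.CDVB, phylum=SuperPhylum.TACK_CRENARCHAEOTA):
    return ProteinArchitecture(
        protein_id=pid, family=family, super_phylum=phylum,
        domains=[DomainInstance(d, 10 * (i + 1), 10 * (i + 1) + 5, Evidence.DB_SCAN)
                 for i, d in enumerate(doms)],
    )


class TestAssemble:
    def test_overlapping_same_type_union_merged(self):
        rows = [
            AnnotationRow("P1", D.SNF7, 10, 60, Evidence.DB_SCAN),
            AnnotationRow("P1", D.SNF7, 40, 90, Evidence.SS_ANNOTATION),
        ]
        (a,) = arch.assemble_architectures(rows)
        assert [(d.domain_type, d.start, d.end, d.evidence) for d in a.domains] == [
            (D.SNF7, 10, 90, Evidence.DB_SCAN)
        ]

    def test_disjoint_same_type_kept_separate(self):
        rows = [
            AnnotationRow("P1", D.MIT, 1, 50, Evidence.DB_SCAN),
            AnnotationRow("P1", D.MIT, 100, 150, Evidence.DB_SCAN),
        ]
        (a,) = arch.assemble_architectures(rows)
        assert len(a.domains) == 2

    def test_mim2_class_precedence_total_over_core(self):
        mm = [
            MotifMatch("P1", "MIM2_Core", 100, 104, "LPKLP", 2),
            MotifMatch("P1", "MIM2_total", 100, 109, "LPKLPKKPLP", 4),
        ]
        (a,) = arch.assemble_architectures([], mm)
        (inst,) = a.domains
        assert inst.domain_type is D.MIM2
        assert inst.qualifier == "MIM2_total" and inst.proline_count == 4

    def test_merge_is_idempotent(self):
        rows = [
            AnnotationRow("P1", D.SNF7, 10, 60, Evidence.DB_SCAN),
            AnnotationRow("P1", D.SNF7, 40, 90, Evidence.DB_SCAN),
            AnnotationRow("P1", D.BWH, 95, 120, Evidence.DB_SCAN),
        ]
        (once,) = arch.assemble_architectures(rows)
        again_rows = [
            AnnotationRow("P1", d.domain_type, d.start, d.end, d.evidence)
            for d in once.domains
        ]
        (twice,) = arch.assemble_architectures(again_rows)
        assert [(d.domain_type, d.start, d.end) for d in twice.domains] == [
            (d.domain_type, d.start, d.end) for d in once.domains
        ]

    def test_unknown_protein_rejected_when_sequences_given(self):
        from cdvkit.types import SequenceRecord

        seqs = [SequenceRecord("P1", "M" * 100)]
        rows = [AnnotationRow("P2", D.SNF7, 1, 10, Evidence.DB_SCAN)]
        with pytest.raises(KeyError, match="P2"):
            arch.assemble_architectures(rows, sequences=seqs)

    def test_protein_without_calls_gets_empty_architecture(self):
        from cdvkit.types import SequenceRecord

        seqs = [SequenceRecord("P1", "M" * 50)]
        (a,) = arch.assemble_architectures([], sequences=seqs)
        assert a.protein_id == "P1" and a.domains == []


class TestFilterCdvc:
    def test_atpase_only_rejected_with_reason(self):
        cand = _arch("C1", [D.AAA_ATPASE], family=Family.CDVC)
        kept, rejected = arch.filter_cdvc([cand])
        assert kept == []
        assert "AAA_ATPase" in rejected[0].reason

    def test_mit_only_kept(self):
        cand = _arch("C1", [D.MIT], family=Family.CDVC)
        kept, rejected = arch.filter_cdvc([cand])
        assert [k.protein.protein_id for k in kept] == ["C1"] and not rejected

    def test_allowlist_exception_kept_with_reason(self):
        cand = _arch("Faci_CdvC", [D.AAA_ATPASE], family=Family.CDVC)
        kept, rejected = arch.filter_cdvc([cand], allowlist={"Faci_CdvC"})
        assert kept[0].reason == "allowlist" and not rejected

    def test_fig1_euryarchaeote_exception_passes_only_via_allowlist(self, fig1_table):
        cdvc = [p for p in fig1_table.proteins if p.family is Family.CDVC]
        kept, rejected = arch.filter_cdvc(cdvc, allowlist={"Faci_CdvC"})
        assert {r.protein.protein_id for r in rejected} <= {
            "Mace_CdvC", "Hvol_CdvC", "Pfur_CdvC"
        }
        assert "Faci_CdvC" in {k.protein.protein_id for k in kept}


class TestClassifyCdvb:
    @pytest.mark.parametrize(
        "doms,expected",
        [
            ([D.SNF7, D.MIM2, D.BWH], ArchitectureClass.CDVB),
            ([D.SNF7, D.MIM2], ArchitectureClass.CDVB12),
            ([D.SNF7], ArchitectureClass.CDVB3),
            ([D.MIM2], ArchitectureClass.UNCLASSIFIED),
        ],
    )
    def test_tack_classes(self, doms, expected):
        assert arch.classify_cdvb(_arch("p", doms)) is expected

    @pytest.mark.parametrize(
        "doms,expected",
        [
            ([D.ANCHR, D.SNF7, D.MIM1], ArchitectureClass.CDVBA1),
            ([D.SNF7, D.MIM2], ArchitectureClass.CDVBA2),
            ([D.MIM1], ArchitectureClass.UNCLASSIFIED),
        ],
    )
    def test_asgard_classes(self, doms, expected):
        a = _arch("p", doms, phylum=SuperPhylum.ASGARD)
        assert arch.classify_cdvb(a) is expected

    def test_cren_fixture_yields_exactly_three_classes(self, fig1_table):
        labels = {
            arch.classify_cdvb(p)
            for p in fig1_table.proteins
            if p.family is Family.CDVB
            and p.super_phylum is SuperPhylum.TACK_CRENARCHAEOTA
        }
        assert labels == {
            ArchitectureClass.CDVB, ArchitectureClass.CDVB12, ArchitectureClass.CDVB3
        }

    def test_asgard_fixture_yields_exactly_two_classes(self, fig1_table):
        labels = {
            arch.classify_cdvb(p)
            for p in fig1_table.proteins
            if p.family is Family.CDVB and p.super_phylum is SuperPhylum.ASGARD
        }
        assert labels == {ArchitectureClass.CDVBA1, ArchitectureClass.CDVBA2}


class TestSharedDomains:
    def test_fig1_three_superphyla_share_four_domains(
        self, fig1_table, superphylum_groups
    ):
        shared = arch.shared_domains(fig1_table, superphylum_groups)
        assert shared == {D.SNF7, D.AAA_ATPASE, D.MIT, D.VPS4_C}

    def test_single_group_gives_union(self, fig1_table):
        orgs = [fig1_table.organisms[0]]
        shared = arch.shared_domains(fig1_table, {"g": orgs})
        assert shared == fig1_table.domain_union(orgs)

    def test_disjoint_groups_share_nothing(self):
        t = ArchitectureTable(
            proteins=[
                _arch("a", [D.SNF7]),
                _arch("b", [D.MIT]),
            ]
        )
        t.proteins[0].organism, t.proteins[1].organism = "o1", "o2"
        t = ArchitectureTable(proteins=t.proteins)
        assert arch.shared_domains(t, {"g1": ["o1"], "g2": ["o2"]}) == set()

    def test_empty_group_rejected(self, fig1_table):
        with pytest.raises(ValueError, match="empty"):
            arch.shared_domains(fig1_table, {"g": []})

    def test_shared_subset_of_every_group_union(self, fig1_table):
        rng = random.Random(11)
        orgs = fig1_table.organisms
        for _ in range(20):
            shuffled = orgs[:]
            rng.shuffle(shuffled)
            cut1, cut2 = rng.randint(1, 49), rng.randint(1, 49)
            lo, hi = min(cut1, cut2), max(cut1, cut2)
            if lo == hi:
                hi += 1
            groups = {
                "a": shuffled[:lo], "b": shuffled[lo:hi], "c": shuffled[hi:]
            }
            if any(not g for g in groups.values()):
                continue
            shared = arch.shared_domains(fig1_table, groups)
            for members in groups.values():
                assert shared <= fig1_table.domain_union(members)


class TestOrganismCounts:
    def test_fig1_counts(self, fig1_table):
        assert arch.organisms_with_homologs(fig1_table) == (37, 14)

    def test_single_empty_organism(self):
        t = ArchitectureTable(organisms=["lonely"])
        assert arch.organisms_with_homologs(t) == (0, 1)

    def test_single_organism_with_cdvb(self):
        p = _arch("p", [D.SNF7])
        p.organism = "org"
        t = ArchitectureTable(proteins=[p])
        assert arch.organisms_with_homologs(t) == (1, 0)


class TestGeneNeighborhood:
    def _coords(self, ranks_by_gene, organism="org"):
        return pd.DataFrame(
            [
                dict(organism=organism, gene_id=g, start=1000 * r)
                for g, r in ranks_by_gene.items()
            ]
        )

    FAMS = {"cdvA": Family.CDVA, "cdvB": Family.CDVB, "cdvC": Family.CDVC}

    def test_adjacent_genes_direct(self):
        coords = self._coords({"x1": 1, "cdvA": 5, "cdvB": 6, "cdvC": 7, "x2": 9})
        assert arch.gene_neighborhood(coords, self.FAMS) == {"org": "direct"}

    def test_gap_of_four_is_close(self):
        coords = self._coords({"cdvA": 5, "x1": 6, "x2": 7, "x3": 8, "cdvC": 9})
        assert arch.gene_neighborhood(coords, self.FAMS) == {"org": "close"}

    def test_far_apart_is_distant(self):
        coords = self._coords(
            {"cdvA": 0, **{f"x{i}": i for i in range(1, 10)}, "cdvC": 10}
        )
        assert arch.gene_neighborhood(coords, self.FAMS) == {"org": "distant"}

    def test_single_cdv_gene_absent(self):
        coords = self._coords({"cdvA": 1, "x1": 2})
        assert arch.gene_neighborhood(coords, self.FAMS) == {"org": "absent"}

    def test_duplicate_coordinates_rejected(self):
        coords = pd.DataFrame(
            [
                dict(organism="org", gene_id="cdvA", start=100),
                dict(organism="org", gene_id="cdvB", start=100),
            ]
        )
        with pytest.raises(ValueError, match="duplicate"):
            arch.gene_neighborhood(coords, self.FAMS)
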