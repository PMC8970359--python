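# cdvkit

Domain-architecture analysis of archaeal Cdv/ESCRT cell-division machineries.

Archaea divide with a machinery related to the eukaryotic ESCRT system: CdvA
(membrane anchor, TACK archaea only), a family of CdvB paralogs (ESCRT-III/Snf7
homologs that polymerize into rings), and CdvC (a Vps4/AAA+ ATPase that
depolymerizes them). Because experiments on most archaea are hard, machinery
differences can be read instead from *protein domain architectures*: which of
eleven building-block domains (CdvA_alpha, CdvA_beta, BWI, BWH, MIM1, MIM2,
Snf7, Vps4_C, MIT, AAA_ATPase, ANCHR) each homolog carries, and which
domain-pair interactions those allow. `cdvkit` implements that analysis as a
reusable pipeline for people studying archaeal cell division, ESCRT evolution,
or minimal synthetic division machineries:

* **motif scanning** — the MIM2 motif classes as regular expressions over the
  hydrophobic class φ = `[AILMFVPGW]` and charged class x = `[RKDE]`:
  `MIM2_Core = φPxφP`, `MIM2_total = φPxφP·xxPφP`, `MIM2_Sulf = xφxxφφPx·φPxφP`;
  proline-rich "putative MIM2" windows; the ANCHR N-terminal membrane helix
  call (a predicted helix run ≥ 8 residues with no helix-breaking proline);
* **architecture classification** — merging overlapping domain calls, the
  CdvC plausibility filter (Vps4_C or MIT required), the CdvB class taxonomy
  (CdvB = {Snf7, MIM2, BWH}, CdvB1/2 = {Snf7, MIM2}, CdvB3 = {Snf7};
  Asgard CdvBa1/CdvBa2 split by ANCHR), per-group summaries and gene
  neighborhood clustering;
* **interaction networks and mechanism inference** — family-level PPI graphs
  justified by domain-pair rules, and a deterministic recursive engine that
  reconstructs assembly/disassembly scenarios (membrane_bind → recruit →
  polymerize → bind → disassemble) with affinity ranking
  (BWI–BWH > Snf7–Snf7 > MIM2–MIT by proline count > Vps4_C–Vps4_C);
* **ancestral reconstruction** — exact maximum-parsimony gain/loss inference
  of domain presence/absence on rooted (possibly multifurcating) trees, with
  Dollo and presence-bias root policies;
* **synthetic data** — seeded generators for motif-planted sequences,
  secondary-structure tracks and gain/loss character evolution, so every
  stage is testable offline. Packaged fixtures transcribe the published
  figure-level survey (51 organisms, 37 with ≥ 1 Cdv homolog).

## Worked example

```python
from cdvkit import interaction, synthetic_data

sets = synthetic_data.make_paper_protein_sets()
net = interaction.build_ppi(sets["Crenarchaeota"], qualitative=True)
print(net.count_validated())
for edge in net.edges:
    print(edge.node_a, "-", edge.node_b, edge.domain_pair, edge.status.value)

(scenario,) = interaction.infer_mechanism(sets["Crenarchaeota"])
for e in scenario.events:
    print(e.step_index, e.kind, e.actor, "->", e.target)
print("unresolved:", sorted(scenario.unresolved))
```

prints

```
4
CdvA - CdvA ('CdvA_beta',) putative
CdvA - CdvB ('BWH', 'BWI') validated
CdvB - CdvB ('Snf7',) validated
CdvB - CdvC ('MIM2', 'MIT') validated
CdvC - CdvC ('Vps4_C',) validated
0 membrane_bind CdvA -> membrane
1 recruit CdvB -> CdvA
2 polymerize CdvB -> ('CdvB1/2', 'CdvB3')
3 bind CdvC -> CdvB
4 disassemble CdvC -> CdvB
5 disassemble CdvC -> CdvB1/2
unresolved: ['CdvB3']
```

The Crenarchaeota ancestral set supports four validated family-level
interactions (the grey CdvA_beta self-polymerization is putative and not
counted). The inferred mechanism is: CdvA binds the membrane, recruits the
BWH-bearing CdvB, the ring polymerizes via Snf7, CdvC binds the
highest-proline MIM2 and depolymerizes CdvB before CdvB1/2; CdvB3 carries no
MIM motif, so no disassembly route exists for it and it is reported
unresolved.

The same commands are available from a shell through the `cdv` console
script (`cdv summarize`, `cdv scan`, `cdv classify`, `cdv ppi`,
`cdv mechanism`, `cdv ancestral`, `cdv simulate`, `cdv io validate`).

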