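import random

import pytest

from cdvkit import io_formats as io
from cdvkit import synthetic_data as sd
from cdvkit.types import PresenceMatrix, RootedTree, TreeNode


@pytest.fixture(scope="session")
def fig1_table():
    return io.load_fixture("fig1_architectures")


@pytest.fixture(scope="session")
def fig5_records():
    return io.load_fixture("fig5_asgard")


@pytest.fixture(scope="session")
def fig6_tree():
    return io.load_fixture("fig6_tree")


@pytest.fixture(scope="session")
def fig6_matrix():
    return io.load_fixture("fig6_matrix")


@pytest.fixture(scope="session")
def paper_sets():
    return sd.make_paper_protein_sets()


@pytest.fixture()
def superphylum_groups(fig1_table):
    """Organisms grouped into the three Cdv-bearing super-phyla (TACK merged)."""
    groups = {}
    for org in fig1_table.organisms:
        sp = fig1_table.super_phyla[org]
        key = "TACK" if sp.is_tack else sp.value
        groups.setdefault(key, []).append(org)
    return groups


def random_polytomous_tree(rng: random.Random, n_leaves: int) -> RootedTree:
    """Random rooted shape over n leaves with node degrees 2-3."""
    nodes = [TreeNode(f"L{i}") for i in range(n_leaves)]
    while len(nodes) > 1:
        k = rng.randint(2, min(3, len(nodes)))
        group = [nodes.pop(rng.randrange(len(nodes))) for _ in range(k)]
        nodes.append(TreeNode("", group))
    return RootedTree(nodes[0])


def single_character_matrix(leaf_states: dict[str, int]) -> PresenceMatrix:
    taxa = list(leaf_states)
    return PresenceMatrix(
        taxa=taxa, characters=["c"], states=[[leaf_states[t]] for t in taxa]
    )
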