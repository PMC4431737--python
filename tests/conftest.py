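import pytest

from functree import MembershipTables, build_tree


@pytest.fixture
def tiny_tables():
    """Smallest mixed case: pathway P {K1,K2}, module M {K1}, K3 unassigned."""
    return MembershipTables(
        ko_to_modules={"K1": frozenset({"M"})},
        ko_to_pathways={"K1": frozenset({"P"}), "K2": frozenset({"P"}),
                        "K3": frozenset()},
        pathway_skeleton={"P": ("proc", "cat")},
        names={"M": "module M", "P": "pathway P"},
    )


@pytest.fixture
def tiny_tree(tiny_tables):
    return build_tree(tiny_tables)


@pytest.fixture
def straddle_tables():
    """Module M {K1,K2} straddling pathways P1 {K1} and P2 {K2}."""
    return MembershipTables(
        ko_to_modules={"K1": frozenset({"M"}), "K2": frozenset({"M"})},
        ko_to_pathways={"K1": frozenset({"P1"}), "K2": frozenset({"P2"})},
        pathway_skeleton={"P1": ("proc", "cat"), "P2": ("proc", "cat")},
        names={"M": "module M", "P1": "pathway P1", "P2": "pathway P2"},
    )
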