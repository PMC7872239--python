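import dendropy
import pytest

from rhosurvey.formats import ReferenceTree


@pytest.fixture
def small_tree() -> ReferenceTree:
    """Balanced 8-leaf tree with unit-ish branch lengths and families."""
    newick = ("(((A:1,B:1):1,(C:1,D:1):1):1,"
              "((E:1,F:1):1,(G:1,H:1):1):1);")
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=True)
    fams = {"A": "xanthorhodopsin", "B": "xanthorhodopsin",
            "C": "halorhodopsin", "D": "proteorhodopsin",
            "E": "halorhodopsin", "F": "halorhodopsin",
            "G": "sensory", "H": "unknown"}
    return ReferenceTree(tree, fams)
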