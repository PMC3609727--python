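from pathlib import Path

import pytest

import radrate as rr

DATA_DIR = Path(__file__).parent / "data"
FIXTURE0 = DATA_DIR / "fixture0"


def tree_signature(node, rel=1e-9):
    """Canonical nested-tuple signature of a tree for equality checks,
    tolerant to float formatting."""
    length = None if node.length is None else round(node.length, 12)
    if node.is_leaf:
        return (node.label, length)
    return (
        tuple(sorted((tree_signature(c) for c in node.children), key=repr)),
        length,
    )


def trees_equal(a: rr.Phylogram, b: rr.Phylogram) -> bool:
    return tree_signature(a.root) == tree_signature(b.root)


@pytest.fixture(scope="session")
def fixture0_paths():
    return {
        "phylogram": FIXTURE0 / "phylogram.nwk",
        "chronogram": FIXTURE0 / "chronogram_true.nwk",
        "alignment": FIXTURE0 / "alignment.fasta",
        "ground_truth": FIXTURE0 / "ground_truth.tsv",
        "config": FIXTURE0 / "sim_config.json",
        "clades": FIXTURE0 / "clades.tsv",
    }


@pytest.fixture()
def three_taxon_tree():
    return rr.Phylogram.from_newick("((A:0.05,B:0.12):0.06,C:0.3);")


@pytest.fixture()
def clock_tree_4tip():
    # every root-to-tip path length is 2.0 substitutions/site
    return rr.Phylogram.from_newick("((A:1.0,B:1.0):1.0,(C:1.5,D:1.5):0.5);")


@pytest.fixture()
def calib_study():
    return rr.CalibrationSpec(25.0, 21.1, 29.3)
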