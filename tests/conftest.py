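import dendropy
import numpy as np
import pytest

from uceflow import msc_simulator as ms
from uceflow.genetree_engine import SubstitutionModel
from uceflow.locus_store import LocusAlignment


def make_locus(rows, locus_id="locus", taxa=None):
    """Alignment from a list of equal-length strings."""
    if taxa is None:
        taxa = tuple(f"t{i}" for i in range(len(rows)))
    return LocusAlignment(locus_id, tuple(taxa),
                          np.array([list(r) for r in rows], dtype="U1"))


def newick(s, ns=None):
    return dendropy.Tree.get(data=s, schema="newick",
                             preserve_underscores=True,
                             taxon_namespace=ns)


@pytest.fixture(scope="session")
def balanced6_model():
    """Six-taxon species tree with long internal branches (little ILS)."""
    return ms.SpeciesTreeModel.from_newick(
        "(((A:1,B:1):3,(C:1,D:1):3):3,(E:1,F:1):6);", subst_scale=0.08)


@pytest.fixture(scope="session")
def strong_locus(balanced6_model):
    """A 600-site locus simulated on one gene tree of the 6-taxon model."""
    gt = ms.simulate_gene_trees(balanced6_model, 1, seed=11)[0]
    profile = ms.LocusProfile(length=600, core_rate=0.05, flank_rate=1.0,
                              missing_prob=0.0, subst_scale=0.08)
    aln, bp = ms.simulate_locus_alignment(gt, profile, seed=4)
    return aln, bp, profile


@pytest.fixture(scope="session")
def hky_model():
    return SubstitutionModel.hky85(2.0, np.array([0.3, 0.2, 0.2, 0.3]))
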