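import pytest

from nanomatch import simulate
from nanomatch.amplicon import Hinge, VhhSequence


def build_protein(cdr1="ADKFGT", cdr2="GHTNM", cdr3="RSTDEFGHK",
                  fr2=simulate.FR2, hinge=Hinge.LONG_IGG2):
    """A VHH protein assembled from the default framework scaffold with
    chosen CDR loops; the true region boundaries are known by construction."""
    return (
        simulate.FR1 + cdr1 + fr2 + cdr2 + simulate.FR3 + cdr3
        + simulate.FR4 + simulate.HINGE_STUB[hinge]
    )


def true_boundaries(cdr1="ADKFGT", cdr2="GHTNM", cdr3="RSTDEFGHK",
                    fr2=simulate.FR2, hinge=Hinge.LONG_IGG2):
    b = [0, len(simulate.FR1)]
    for seg in (cdr1, fr2, cdr2, simulate.FR3, cdr3,
                simulate.FR4 + simulate.HINGE_STUB[hinge]):
        b.append(b[-1] + len(seg))
    return {
        "FR1": (b[0], b[1]), "CDR1": (b[1], b[2]), "FR2": (b[2], b[3]),
        "CDR2": (b[3], b[4]), "FR3": (b[4], b[5]), "CDR3": (b[5], b[6]),
        "FR4": (b[6], b[7]),
    }


def make_vhh(protein, count=1, hinge=Hinge.LONG_IGG2, id=None):
    from nanomatch.amplicon import _stable_id
    return VhhSequence(
        id=id or _stable_id(protein), protein=protein, dna="", count=count, hinge=hinge
    )


@pytest.fixture
def template_protein():
    return build_protein()


@pytest.fixture
def tiny_sim_config():
    """A fast, small but fully featured simulation configuration."""
    return simulate.SimConfig(
        n_clones=20, n_binders=2, n_read_pairs=300, seed=11
    )
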