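import numpy as np
import pytest

from cnbdkit import (Atom, Chain, Residue, StructureModel, build_polyalanine,
                     build_purine_nucleotide, vp_itc_design)


@pytest.fixture
def rng():
    return np.random.default_rng(20260901)


@pytest.fixture
def helix():
    """30-residue ideal poly-alanine helix (all omega = 180)."""
    return build_polyalanine(30)


@pytest.fixture
def nucleotide_pocket():
    """A syn nucleotide with a three-residue probe 'pocket' around it.

    The probe chain carries one N at hydrogen-bond range from N7, one C at
    van-der-Waals range from C8 and one S at extended-hydrogen-bond range,
    so every contact class is represented.
    """
    lig = build_purine_nucleotide(45.0, base="guanine")
    n7 = lig.atom("N7").position
    c8 = lig.atom("C8").position
    c5 = lig.atom("C5").position
    normal = np.cross(c8 - n7, c5 - n7)
    normal /= np.linalg.norm(normal)
    probe = [
        Residue(name="THR", seq_number=193, atoms=[
            Atom(name="N", element="N", position=n7 + 2.8 * normal)]),
        Residue(name="MET", seq_number=175, atoms=[
            Atom(name="CE", element="C", position=c8 + 3.7 * normal)]),
        Residue(name="CYS", seq_number=173, atoms=[
            Atom(name="SG", element="S", position=n7 - 3.4 * normal)]),
    ]
    model = StructureModel(chains=[Chain("A", probe), Chain("L", [lig])])
    return model, lig


@pytest.fixture
def paper_design():
    """15 uM cell, 250 uM syringe, 28 x 5 uL at 30 C in a 1.43 mL cell."""
    return vp_itc_design()
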