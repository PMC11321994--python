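import numpy as np
import pytest

from photobo.chemspace import Substituent, SubstituentSet, enumerate_library
from photobo.conditions import CatalystEntry, LigandEntry, build_condition_space


@pytest.fixture(scope="session")
def tiny_substituents():
    ra = [Substituent("Ra01", "ED", "C"), Substituent("Ra02", "EW", "C#N"),
          Substituent("Ra03", "X", "Cl")]
    rb = [Substituent("Rb01", "PAH", "c2ccccc2"),
          Substituent("Rb02", "PAH", "c2ccc(C)cc2"),
          Substituent("Rb03", "PA", "c2ccc(N)cc2"),
          Substituent("Rb04", "CZ", "n2c3ccccc3c3ccccc32")]
    return SubstituentSet(ra=ra, rb=rb)


@pytest.fixture(scope="session")
def tiny_space():
    """A 3 x 2 x 4 = 24-condition formulation space with real fingerprints."""
    cats = [
        CatalystEntry("M1", "N#Cc1ccccc1", -1.4),
        CatalystEntry("M2", "N#Cc1ccc(C)cc1", -1.6),
        CatalystEntry("M3", "N#Cc1ccc(OC)cc1", -1.9),
    ]
    ligs = [LigandEntry("L1", "c1ccncc1"), LigandEntry("L2", "c1cc(C)ccn1")]
    return build_condition_space(cats, ligs, [1, 4, 7, 10])


@pytest.fixture(scope="session")
def small_library(tiny_substituents):
    return enumerate_library(tiny_substituents)
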