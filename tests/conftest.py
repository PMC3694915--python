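import sys
from itertools import combinations
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from platydate import datasets, simulate, traits


@pytest.fixture(scope="session")
def trait_table():
    return datasets.trait_table()


@pytest.fixture(scope="session")
def quad_fit(trait_table):
    return traits.fit_quadratic(trait_table, subset="platyrrhini")


#: chronogram with an outgroup, used by pipeline/recovery tests: New World
#: monkey crown at 24.4 Ma, catarrhine crown at 29.2 Ma, anthropoid root at
#: 44.3 Ma; platyrrhine edges ḡ=16 yr, great-ape tip edges 27 yr
STUDY_NEWICK_WITH_OUTGROUP = (
    "(((((Saimiri:18.7,Callithrix:18.7)Cebidae:4.2,"
    "(Ateles:12.0,Alouatta:12.0)Atelidae:10.9)AtelidCebid:1.5,"
    "Callicebus:24.4)Platyrrhini:19.9,"
    "((Homo:8.8,Pan:8.8)HomoPan:20.4,Macaca:29.2)Catarrhini:15.1)Anthropoidea:15.7,"
    "Tarsius:60.0)Root;"
)

STUDY_GENTIMES = {
    "Homo": 27.0, "Pan": 27.0, "HomoPan": 24.0, "Macaca": 24.0,
    "Catarrhini": 19.5, "Tarsius": 16.0,
}

PLATYRRHINE_TIPS = ["Saimiri", "Callithrix", "Ateles", "Alouatta", "Callicebus"]
CATARRHINE_TIPS = ["Homo", "Pan", "Macaca"]

STUDY_NODES = {
    "Crown Platyrrhini": PLATYRRHINE_TIPS,
    "Atelidae branching": ["Saimiri", "Callithrix", "Ateles", "Alouatta"],
    "Crown Cebidae": ["Saimiri", "Callithrix"],
    "Crown Anthropoidea": PLATYRRHINE_TIPS + CATARRHINE_TIPS,
    "Crown Catarrhini": CATARRHINE_TIPS,
    "Homo/Pan": ["Homo", "Pan"],
    "Atelinae": ["Ateles", "Alouatta"],
}

#: relative-rate screen pairs comparing like with like (same generation time)
WITHIN_CLADE_PAIRS = list(combinations(PLATYRRHINE_TIPS, 2)) + list(
    combinations(CATARRHINE_TIPS, 2)
)


@pytest.fixture(scope="session")
def study_truth():
    return simulate.build_truth(
        STUDY_NEWICK_WITH_OUTGROUP,
        generation_times=dict(STUDY_GENTIMES),
        default_generation_time=16.0,
    )


def clade_value(mapping, members):
    """Value for the smallest tip set containing ``members`` (the LCA)."""
    return min((len(k), v) for k, v in mapping.items() if set(members) <= k)[1]
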