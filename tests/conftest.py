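import numpy as np
import pandas as pd
import pytest

import chronodiv as cd

TOY_NEWICK = "((A:1,B:1):1,C:2);"


@pytest.fixture(scope="session")
def toy_tree() -> cd.Chronogram:
    """3-tip caterpillar: d(A,B)=1, d(A,C)=d(B,C)=2, X=5."""
    return cd.read_newick(TOY_NEWICK)


@pytest.fixture(scope="session")
def balanced4() -> cd.Chronogram:
    return cd.read_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def toy_occ() -> cd.OccurrenceMatrix:
    """Two sites over the toy tree: s1={A,B}, s2={A,C}."""
    pres = pd.DataFrame({"s1": [1, 1, 0], "s2": [1, 0, 1]}, index=["A", "B", "C"])
    meta = pd.DataFrame(
        {"island": ["isl1", "isl2"], "habitat": ["inner_reef", "outer_slope"]},
        index=["s1", "s2"],
    )
    return cd.OccurrenceMatrix(pres, meta)


@pytest.fixture(scope="session")
def random_trees():
    """A pool of small simulated pure-birth trees for property checks."""
    trees = []
    for s in range(100):
        t = cd.simulate_yule_tree(cd.ConstantRate(0.15), duration=20.0, seed=s)
        if t.n >= 3:
            trees.append(t)
    return trees
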