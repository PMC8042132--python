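import numpy as np
import pandas as pd
import pytest

import guiltnet as gn


@pytest.fixture(scope="session")
def scenario():
    """One fixed synthetic study shared by end-to-end tests."""
    return gn.demo_scenario(seed=7)


@pytest.fixture
def small_expr():
    rng = np.random.default_rng(11)
    return pd.DataFrame(
        rng.normal(size=(6, 8)),
        index=pd.Index([f"g{i}" for i in range(6)], name="gene_id"),
        columns=[f"s{j}" for j in range(8)],
    )


@pytest.fixture
def tiny_thesaurus():
    return gn.Thesaurus(
        [
            gn.ThesaurusEntry("T1", "gene", "CD151", ("cd-151",)),
            gn.ThesaurusEntry("T2", "gene", "integrin", ("itg",)),
            gn.ThesaurusEntry("T3", "gene", "integrin alpha 9", ("itga9",)),
            gn.ThesaurusEntry("D1", "disease", "atherosclerosis", ("athero",)),
            gn.ThesaurusEntry("P1", "phenotype", "blood pressure", ("bp",)),
        ]
    )
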