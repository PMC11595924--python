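import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import pegscreen as ps

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_table(records) -> ps.StudyTable:
    return ps.StudyTable(
        pd.DataFrame(
            records,
            columns=["accession", "treatment", "replicate", "trait", "value"],
        )
    )


@pytest.fixture
def toy_table() -> ps.StudyTable:
    """3 accessions x 3 treatments x 2 replicates of GP, RL and SL, with a
    clear tolerance ordering A > B > C under stress."""
    base = {"GP": {"A": 95.0, "B": 85.0, "C": 75.0},
            "RL": {"A": 9.0, "B": 8.0, "C": 7.0},
            "SL": {"A": 7.0, "B": 6.5, "C": 6.0}}
    drop = {"T0": 1.0, "T1": 0.8, "T2": 0.6}
    tol = {"A": 1.0, "B": 0.5, "C": 0.0}
    rows = []
    for trait, levels in base.items():
        for acc, mu in levels.items():
            for code, d in drop.items():
                # tolerant accessions lose less under stress
                mult = 1.0 - (1.0 - d) * (1.0 - 0.5 * tol[acc])
                for rep, eps in ((1, -0.1), (2, 0.1)):
                    rows.append((acc, code, rep, trait, mu * mult + eps))
    return make_table(rows)


@pytest.fixture(scope="session")
def default_sim():
    """One draw of the default calibrated design, shared across tests."""
    return ps.generate(ps.default_paper_like_config())
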