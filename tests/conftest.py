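import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from _testutil import TinyProblem  # noqa: E402


@pytest.fixture()
def four_token_problem() -> TinyProblem:
    """Fixed tiny instance: 2 samples × 2 tokens, K=L=2, C=4, J=2.

    Sample 0 uses compounds {0,1}, sample 1 uses {2,3}, so the posterior
    has clear structure while the moderate concentrations (0.5) keep the
    chain mixing fast.
    """
    tokens = [
        [([0, 0], [1, 1]), ([0, 1], [1, 0])],
        [([2, 2], [3, 3]), ([2, 3], [3, 2])],
    ]
    return TinyProblem(tokens, C=4, K=2, L=2, a_th=0.5, a_ph=0.5, a_de=0.5, a_ga=0.5)


@pytest.fixture()
def catalog_file(tmp_path):
    path = tmp_path / "catalog.tsv"
    path.write_text(
        "# reaction_id\tsubstrates\tproducts\n"
        "R1\tC1,C2\tC3\n"
        "R2\tC3\tC4\n"
        "R3\tC1\tC1\n"
    )
    return path
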