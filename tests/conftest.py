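import random
from pathlib import Path

import pytest

from regsp.formats import HSP
from regsp.synth import worked_example_hsps

DATA = Path(__file__).parent / "data"


@pytest.fixture
def data_dir() -> Path:
    return DATA


@pytest.fixture
def worked_example():
    """The worked-example HSPs, fresh per test."""
    return worked_example_hsps()


def random_hsps(rng: random.Random, n: int, contig="c", ref="r") -> list[HSP]:
    """Random HSP instances on one (contig, reference) pair."""
    out = []
    for i in range(n):
        start = rng.randint(1, 500)
        end = start + rng.randint(30, 300)
        out.append(
            HSP(
                contig_id=contig,
                ref_id=ref,
                gene_id=f"g{i}",
                q_start=start,
                q_end=end,
                s_start=1,
                s_end=(end - start + 1) // 3 or 1,
                frame=rng.choice([-3, -2, -1, 1, 2, 3]),
                align_len=(end - start + 1) // 3 or 1,
                pident=rng.uniform(40, 100),
                evalue=10.0 ** -rng.randint(3, 60),
                bitscore=float(rng.choice([50, 80, 100, 120, 150, 200])),
            )
        )
    return out
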