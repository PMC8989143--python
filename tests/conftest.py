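import numpy as np
import pytest

from bovibuccal.io import Lineage
from bovibuccal.simulate import generate_references, scenario_lineages


@pytest.fixture(scope="session")
def small_reference_set():
    """Six well-separated 16S-like references with lineages."""
    taxa = [f"shared_{i:03d}" for i in range(4)] + ["oral_000", "rumen_000"]
    templates = generate_references(taxa, seed=11)
    lineages = scenario_lineages(taxa)
    return {t: (templates[t].sequence, lineages[t]) for t in taxa}, templates


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


def make_lineage(genus: str = "Prevotella", species: str = "sp") -> Lineage:
    return Lineage.parse(
        "d__Bacteria;p__Bacteroidota;c__Bacteroidia;o__Bacteroidales;"
        f"f__Prevotellaceae;g__{genus};s__{species}"
    )
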