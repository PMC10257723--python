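import numpy as np
import pytest
from scipy import sparse

from homdeficit.panel import CohortPanel, PopulationPanel


def panel_from_arrays(pops: dict[str, tuple[np.ndarray, np.ndarray]],
                      variant_ids=None) -> CohortPanel:
    """Build a panel from dense (hap_a, hap_b) 0/1 arrays per population."""
    first = next(iter(pops.values()))
    m = np.atleast_2d(first[0]).shape[1]
    if variant_ids is None:
        variant_ids = [f"v{j}" for j in range(m)]
    populations = [
        PopulationPanel(name=name,
                        hap_a=sparse.csc_matrix(np.atleast_2d(a)),
                        hap_b=sparse.csc_matrix(np.atleast_2d(b)))
        for name, (a, b) in pops.items()
    ]
    return CohortPanel(variant_ids=np.asarray(variant_ids, dtype=object),
                       populations=populations)


def panel_from_genotypes(genotypes: dict[str, list[list[str]]],
                         variant_ids=None) -> CohortPanel:
    """Build a panel from phased genotype strings.

    ``genotypes[pop][i]`` lists the genotypes ("0|1", ...) of individual i,
    one per variant.
    """
    pops = {}
    for name, rows in genotypes.items():
        a = np.array([[int(g.split("|")[0]) for g in row] for row in rows])
        b = np.array([[int(g.split("|")[1]) for g in row] for row in rows])
        pops[name] = (a, b)
    return panel_from_arrays(pops, variant_ids)


@pytest.fixture
def toy_panel() -> CohortPanel:
    """Two 3-individual populations over three variants."""
    return panel_from_genotypes({
        "P1": [["0|1", "0|0", "1|1"],
               ["0|0", "0|1", "0|1"],
               ["1|1", "0|0", "0|0"]],
        "P2": [["0|0", "1|1", "0|0"],
               ["0|1", "0|0", "1|1"],
               ["0|0", "0|0", "0|0"]],
    }, variant_ids=["va", "vb", "vc"])
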