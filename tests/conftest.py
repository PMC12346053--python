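import numpy as np
import pandas as pd
import pytest

from hrrscan.genotype_io import HET, HOM_A, HOM_B, MISSING, GenotypeDataset
from hrrscan.simulate import emit_fixture

CODE = {"A": HOM_A, "H": HET, "B": HOM_B, ".": MISSING}


def dataset_from_strings(
    genos,
    positions=None,
    chroms=None,
    herds=None,
    spacing=60_000,
):
    """Build a GenotypeDataset from genotype strings.

    Each string is one individual; characters: A = hom allele A, H = het,
    B = hom allele B, . = missing.  Default positions are evenly spaced so
    any 2-marker stretch clears a 50 kb length minimum.
    """
    n_markers = len(genos[0])
    assert all(len(g) == n_markers for g in genos)
    if positions is None:
        positions = [(i + 1) * spacing for i in range(n_markers)]
    if chroms is None:
        chroms = [1] * n_markers
    if herds is None:
        herds = ["herd1"] * len(genos)
    calls = np.array(
        [[CODE[c] for c in g] for g in genos], dtype=np.int8
    )
    markers = pd.DataFrame(
        {
            "chromosome": np.asarray(chroms, dtype=np.int64),
            "marker_id": [f"m{i}" for i in range(n_markers)],
            "position_bp": np.asarray(positions, dtype=np.int64),
            "allele_a": "A",
            "allele_b": "C",
        }
    )
    individuals = pd.DataFrame(
        {
            "individual_id": [f"ind{i}" for i in range(len(genos))],
            "herd_id": herds,
            "pseudo_phenotype": [str(i + 1) for i in range(len(genos))],
        }
    )
    return GenotypeDataset(markers=markers, calls=calls,
                           individuals=individuals)


@pytest.fixture(scope="session")
def mini_island():
    return emit_fixture("mini-island")


@pytest.fixture(scope="session")
def mini_null():
    return emit_fixture("mini-null")


@pytest.fixture(scope="session")
def mini_roh():
    return emit_fixture("mini-roh")
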