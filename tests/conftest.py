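import numpy as np
import pandas as pd
import pytest

from apppre import data
from apppre.conservation import PromoterAlignment, TaxonomyTable
from apppre.effectsize import AssayTable


@pytest.fixture
def worked_example():
    """Published adjusted means and anchor effect sizes (k=8, n=3)."""
    return data.WORKED_EXAMPLE


@pytest.fixture
def single_film_table():
    """One film, three variants, signals {WT:2, A:1, B:3}."""
    df = pd.DataFrame({
        "film_id": ["f1"] * 3,
        "variant": ["WT", "A", "B"],
        "replicate": [1, 1, 1],
        "signal": [2.0, 1.0, 3.0],
    })
    return AssayTable("toy", "subtractive", df, "WT")


def make_film_table(signals_by_film, control="WT"):
    """Build a subtractive AssayTable from {film: {variant: signal}}."""
    rows = []
    for film, sig in signals_by_film.items():
        for v, x in sig.items():
            rows.append((film, v, 1, float(x)))
    df = pd.DataFrame(rows, columns=["film_id", "variant", "replicate",
                                     "signal"])
    return AssayTable("toy", "subtractive", df, control)


@pytest.fixture
def toy_alignment():
    """Four species, 12 columns with known per-column composition."""
    ids = ["human", "chimp", "mouse", "opossum"]
    seqs = [
        "ACGTACGTACGT",
        "ACGTACGTACGT",
        "ACGAACGTTCGT",
        "ACG-ACGTTTTT",
    ]
    tax = TaxonomyTable(pd.DataFrame({
        "species": ids,
        "clade": ["primates", "primates", "euarchontoglires", "mammals"],
        "base_weight": [2, 2, 2, 1],
        "accession": ["synthetic"] * 4,
    }))
    aln = PromoterAlignment(ids, seqs, reference="human", ref_start=-6)
    return aln, tax
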