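import numpy as np
import pandas as pd
import pytest

from estuarch.tables import FeatureTable, SampleMetadata, TaxonomyMap


@pytest.fixture
def toy_table() -> FeatureTable:
    """6 samples x 5 features with hand-checkable counts."""
    data = pd.DataFrame(
        [
            [10, 0, 5, 0, 85],
            [20, 1, 0, 4, 75],
            [0, 2, 5, 0, 93],
            [5, 0, 0, 6, 89],
            [15, 3, 5, 0, 77],
            [0, 0, 0, 2, 98],
        ],
        index=[f"s{i}" for i in range(1, 7)],
        columns=[f"Z{i}" for i in range(1, 6)],
    )
    return FeatureTable(data)


@pytest.fixture
def mixed_taxonomy() -> TaxonomyMap:
    rows = {
        "Z1": ("Archaea", "Thermoproteota", "Nitrososphaeria", "Nitrosopumilales",
               "Nitrosopumilaceae", "Nitrosopumilus"),
        "Z2": ("Archaea", "Thermoplasmatota", "Poseidoniia", "Poseidoniales",
               "Poseidoniaceae", "Poseidonia"),
        "Z3": ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Pseudomonadales",
               "Halieaceae", "Halioglobus"),
        "Z4": ("Bacteria", "Cyanobacteria", "Cyanobacteriia", "Chloroplast",
               "Chloroplast", "Chloroplast"),
        "Z5": ("Bacteria", "Bacteroidota", "Bacteroidia", "Flavobacteriales",
               "Flavobacteriaceae", "Polaribacter"),
    }
    return TaxonomyMap(
        pd.DataFrame.from_dict(rows, orient="index", columns=list(TaxonomyMap.RANKS))
    )


@pytest.fixture
def design_metadata() -> SampleMetadata:
    df = pd.DataFrame(
        {
            "estuary": ["A"] * 3 + ["B"] * 3,
            "season": ["W", "S", "W", "S", "W", "S"],
            "station": ["L"] * 6,
            "temperature": [5.0, 25.0, 6.0, 26.0, 4.0, 24.0],
        },
        index=[f"s{i}" for i in range(1, 7)],
    )
    return SampleMetadata(df)
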