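import numpy as np
import pytest

from racoon.data_model import VariantTable, VariantRecord
from racoon.node_calibration import CalibrationConfig, fit_racoon
from racoon.synthetic_data import paper_like_config, generate_table


@pytest.fixture
def toy_records():
    return [
        VariantRecord("P1", 10, "A", "V", -3.5, 1, {"ppi": True, "disordered": False}),
        VariantRecord("P1", 20, "C", "Y", -8.1, 0, {"ppi": None, "disordered": True}),
        VariantRecord("P2", 5, "M", "T", -1.2, None, {"ppi": False, "disordered": False}),
    ]


@pytest.fixture
def toy_table(toy_records):
    return VariantTable.from_records(toy_records, ["ppi", "disordered"])


def labeled_table(scores, labels, protein_ids=None, **attr_columns):
    """Build a minimal labeled table from parallel arrays."""
    import pandas as pd

    n = len(scores)
    df = pd.DataFrame({
        "protein_id": protein_ids if protein_ids is not None else ["P1"] * n,
        "position": np.arange(1, n + 1),
        "wt": ["A"] * n,
        "mut": ["V"] * n,
        "score": np.asarray(scores, dtype=float),
        "label": np.asarray(labels, dtype=float),
    })
    for name, vals in attr_columns.items():
        df[name] = np.asarray(vals, dtype=float)
    return VariantTable(df, list(attr_columns))


@pytest.fixture(scope="session")
def synthetic_table():
    """Mid-sized table drawn from the default subgroup preset."""
    return generate_table(paper_like_config(n_variants=50_000, seed=11))


@pytest.fixture(scope="session")
def fitted_model(synthetic_table):
    return fit_racoon(synthetic_table, CalibrationConfig(seed=11))


@pytest.fixture(scope="session")
def held_out_table():
    return generate_table(paper_like_config(n_variants=20_000, seed=1234))
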