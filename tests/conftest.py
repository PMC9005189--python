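import numpy as np
import pandas as pd
import pytest

from couplemap.data_io import MEASUREMENT_COLUMNS, human_panel


@pytest.fixture(scope="session")
def panel():
    return human_panel()


_ROW_DEFAULTS = {
    "source": "src",
    "ligand": "lig",
    "ligand_type": "endogenous",
    "ligand_shared": True,
    "pec50": 7.0,
    "emax": 100.0,
    "basal_mean": 10.0,
    "basal_sd": 2.0,
    "curve_status": "converged",
    "enzymatic_units": False,
    "exclusion": "none",
}


def make_measurements(rows):
    """Build a canonical measurement frame from partial row dicts."""
    full = []
    for row in rows:
        rec = dict(_ROW_DEFAULTS)
        rec.update(row)
        full.append(rec)
    df = pd.DataFrame(full)
    return df[MEASUREMENT_COLUMNS]


def grid(data, receptors, units):
    """Receptor x unit grid from a nested list (None = untested)."""
    return pd.DataFrame(
        np.array([[np.nan if v is None else float(v) for v in row]
                  for row in data]),
        index=receptors, columns=units)


@pytest.fixture
def toy_annotations():
    return pd.DataFrame({
        "receptor": ["H1", "B2AR", "B2AR"],
        "family": ["Gq/11", "Gs", "Gi/o"],
        "rank": ["primary", "primary", "secondary"],
    })
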