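import numpy as np
import pandas as pd
import pytest

from halfcell import skew as hskew
from halfcell.synthetic import SimConfig, generate_experiment


def skew_chain(matrix, sheet, min_mean_tpm=1.0, max_dispersion=2.0):
    """Run adjust -> filter -> skew, returning (adjusted_retained, skew, report)."""
    adjusted = hskew.log1_adjust(matrix)
    report = hskew.filter_genes(matrix, adjusted, min_mean_tpm, max_dispersion)
    retained = report.index[report["retained"]]
    adj_retained = hskew.AdjustedMatrix(
        values=adjusted.values.loc[retained], offsets=adjusted.offsets
    )
    return adj_retained, hskew.compute_skew(adj_retained, sheet), report


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_genes=300,
        n_pairs_control=4,
        n_pairs_kd=4,
        frac_regionalized=0.2,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return generate_experiment(small_config)


@pytest.fixture(scope="session")
def default_experiment():
    return generate_experiment(SimConfig(seed=11))


@pytest.fixture()
def toy_sheet():
    rows = []
    for cond, pairs in (("control", ["c1", "c2"]), ("kd", ["k1", "k2"])):
        for p in pairs:
            for half in "AP":
                rows.append(
                    {"sample_id": f"{p}_{half}", "pair_id": p, "half": half,
                     "condition": cond, "batch": "b1"}
                )
    return pd.DataFrame(rows)


def adjusted_from_values(values: pd.DataFrame) -> hskew.AdjustedMatrix:
    """Wrap pre-adjusted values directly (offsets 0) for unit tests."""
    offsets = pd.Series(0.0, index=values.columns, name="offset")
    return hskew.AdjustedMatrix(values=values, offsets=offsets)
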