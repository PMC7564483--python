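import numpy as np
import pandas as pd
import pytest

from mirsig import CountMatrix, SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A scaled-down cohort for fast unit tests (full design ratios kept)."""
    return SimConfig(n_mirnas=200, ddpcr_panel_extra=10, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture
def toy_counts() -> CountMatrix:
    """Four libraries at equal depth: many flat rows pin the size factors at 1,
    one row doubled in cases."""
    rows = {f"flat{i}": [100, 100, 100, 100] for i in range(9)}
    rows["target"] = [10, 10, 20, 20]
    counts = pd.DataFrame.from_dict(rows, orient="index",
                                    columns=["c1", "c2", "p1", "p2"])
    group = pd.Series(["CONTROL", "CONTROL", "CASE", "CASE"],
                      index=counts.columns)
    return CountMatrix(counts=counts, group=group)


def make_ddpcr(values: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Long-form ddPCR frame from {sample: {mirna: copies_per_ul}}."""
    rows = [
        {"sample_id": s, "mirna_id": m, "copies_per_ul": v}
        for s, per in values.items()
        for m, v in per.items()
    ]
    return pd.DataFrame(rows)


def make_meta(controls: list[str], cases: list[str],
              kras: dict[str, str] | None = None) -> pd.DataFrame:
    kras = kras or {}
    idx = controls + cases
    return pd.DataFrame(
        {
            "group": ["CONTROL"] * len(controls) + ["CASE"] * len(cases),
            "kras_status": [kras.get(s, "NA") for s in idx],
        },
        index=pd.Index(idx, name="sample_id"),
    )


rng_seed = np.random.default_rng  # convenience re-export for tests
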