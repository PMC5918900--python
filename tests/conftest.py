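import numpy as np
import pandas as pd
import pytest

from clonalherit.dataset import OtuDataset
from clonalherit.simulate import SyntheticConfig, make_fixture, simulate_dataset


def build_dataset(counts: dict[str, dict[str, int]], meta: dict[str, dict],
                  phylum: dict[str, str] | None = None) -> OtuDataset:
    """Hand-build a small OtuDataset from nested dicts (sample -> otu -> count)."""
    cdf = pd.DataFrame(counts).T.fillna(0).astype(np.int64)
    cdf.index.name = "sample_id"
    cdf.columns.name = "otu_id"
    tax = pd.DataFrame({"kingdom": "Bacteria",
                        "phylum": pd.Series(phylum or {o: "unknown" for o in cdf.columns})})
    tax = tax.reindex(cdf.columns).fillna("unknown")
    tax.index.name = "otu_id"
    mdf = pd.DataFrame(meta).T
    mdf.index.name = "sample_id"
    for col in ("ecotype", "stolon"):
        mdf[col] = pd.to_numeric(mdf[col], errors="coerce").astype("Int64")
    mdf = mdf[["ecotype", "role", "position", "stolon", "marker"]]
    return OtuDataset(cdf, tax, mdf)


def meta_row(ecotype=1, role="mother_root", position="M", stolon=None, marker="bacteria_16S"):
    return {"ecotype": ecotype, "role": role, "position": position,
            "stolon": stolon, "marker": marker}


@pytest.fixture(scope="session")
def tiny():
    return make_fixture("tiny")


@pytest.fixture(scope="session")
def study():
    return simulate_dataset(SyntheticConfig(seed=2024))


@pytest.fixture
def toy_network():
    """One ecotype, 5 OTUs, mother + 4 daughters + 1 control: hand-checkable."""
    counts = {
        "m": {"o1": 5, "o2": 1, "o3": 2, "o4": 3},
        "d11": {"o1": 2, "o2": 1},
        "d21": {"o1": 1},
        "d12": {"o2": 4},
        "d22": {"o5": 7},
        "ctrl": {"o3": 9},
    }
    meta = {
        "m": meta_row(),
        "d11": meta_row(role="daughter_root", position="D1", stolon=1),
        "d21": meta_row(role="daughter_root", position="D2", stolon=1),
        "d12": meta_row(role="daughter_root", position="D1", stolon=2),
        "d22": meta_row(role="daughter_root", position="D2", stolon=2),
        "ctrl": meta_row(ecotype=None, role="control_substrate", position="NA"),
    }
    return build_dataset(counts, meta)
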