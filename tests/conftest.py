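import logging

import numpy as np
import pandas as pd
import pytest

from methewas import (
    CellReference, MethylationMatrix, ProbeManifest, RawIntensitySet,
    SimulationConfig, simulate_cohort,
)

logging.getLogger("methewas").setLevel(logging.ERROR)


def small_config(seed=11, **kw):
    """A desk-scale cohort: 84 children, 800 probes, 8 slides."""
    defaults = dict(n_unexposed=60, n_exposed=20, n_early_only=4,
                    n_probes=800, n_negative_controls=60, n_slides=8,
                    seed=seed)
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_cohort():
    return simulate_cohort(small_config(), keep_truth=True)


@pytest.fixture(scope="session")
def tiny_clean_cohort():
    """No planted QC failures: every cell should pass the filters."""
    return simulate_cohort(small_config(failed_probe_fraction=0.0,
                                        low_bead_fraction=0.0),
                           keep_truth=True)


@pytest.fixture()
def toy_manifest():
    table = pd.DataFrame({
        "chromosome": ["1", "2", "3", "X", "7", "8"],
        "position": [100, 200, 300, 400, 500, 600],
        "gene": ["G1", "", "G3", "", "G5", ""],
        "design_type": ["I", "I", "II", "II", "I", "II"],
        "channel": ["red", "green", "both", "both", "red", "both"],
        "cgi_relation": ["island", "s_shore", "open_sea", "shelf",
                         "n_shore", "island"],
    }, index=pd.Index([f"cg{i:06d}" for i in range(6)], name="probe_id"))
    return ProbeManifest(table)


def toy_raw(n_probes=20, n_samples=6, n_neg=12, seed=0, manifest=None):
    """Hand-sized RawIntensitySet with strong signal over background 100."""
    rng = np.random.default_rng(seed)
    samples = pd.Index([f"S{j}" for j in range(n_samples)])
    probes = (manifest.probe_ids if manifest is not None
              else pd.Index([f"cg{i:06d}" for i in range(n_probes)],
                            name="probe_id"))
    n_probes = len(probes)
    beta = rng.uniform(0.05, 0.95, size=(n_probes, n_samples))
    total = 5000.0
    meth = total * beta + 100.0
    unmeth = total * (1 - beta) + 100.0
    beads = np.full((n_probes, n_samples), 10)
    neg = pd.Index([f"neg{i}" for i in range(n_neg)], name="control_id")
    ctl_red = rng.normal(100, 20, size=(n_neg, n_samples)).clip(0)
    ctl_green = rng.normal(100, 20, size=(n_neg, n_samples)).clip(0)
    return RawIntensitySet(
        meth=pd.DataFrame(meth, index=probes, columns=samples),
        unmeth=pd.DataFrame(unmeth, index=probes, columns=samples),
        beads=pd.DataFrame(beads, index=probes, columns=samples),
        controls_red=pd.DataFrame(ctl_red, index=neg, columns=samples),
        controls_green=pd.DataFrame(ctl_green, index=neg, columns=samples),
        control_type=pd.Series("negative", index=neg))


def beta_matrix(values: np.ndarray, prefix="cg") -> MethylationMatrix:
    probes = pd.Index([f"{prefix}{i:06d}" for i in range(values.shape[0])],
                      name="probe_id")
    samples = pd.Index([f"S{j}" for j in range(values.shape[1])])
    df = pd.DataFrame(values, index=probes, columns=samples)
    return MethylationMatrix(values=df, scale="beta", mask=df.notna())
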