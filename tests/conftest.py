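import numpy as np
import pandas as pd
import pytest

from ecgxai.datamodel import PairedDataset
from ecgxai.schema import ParameterSchema, SchemaEntry, default_schema
from ecgxai.synthetic import GeneratorConfig, generate_population


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def small_population():
    """~800-record population with all five phenotypes planted."""
    return generate_population(GeneratorConfig(n_patients=400, seed=11))


def tiny_schema(p: int = 3) -> ParameterSchema:
    """Minimal schema of p R-amplitude-like parameters for plumbing tests."""
    leads = ["I", "II", "III", "aVR", "aVL", "aVF", "V1", "V2", "V3", "V4", "V5", "V6"]
    return ParameterSchema([
        SchemaEntry(f"x{i}", leads[i % 12], "R_amp", "mV") for i in range(p)
    ])


def tiny_dataset(lvef, paced=None, patient_ids=None, p: int = 3,
                 values=None) -> PairedDataset:
    """Construct a PairedDataset from label/metadata vectors alone."""
    n = len(lvef)
    sch = tiny_schema(p)
    rng = np.random.default_rng(0)
    df = pd.DataFrame(values if values is not None else rng.standard_normal((n, p)),
                      columns=sch.names)
    df.insert(0, "lvef", np.asarray(lvef, dtype=float))
    df.insert(0, "days_to_echo", 0)
    df.insert(0, "paced", np.zeros(n, bool) if paced is None else np.asarray(paced))
    df.insert(0, "patient_id", patient_ids if patient_ids is not None
              else [f"P{i}" for i in range(n)])
    df.insert(0, "record_id", [f"E{i}" for i in range(n)])
    return PairedDataset(df, schema=sch)
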