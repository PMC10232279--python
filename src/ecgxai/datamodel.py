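"""Paired ECG-parameter / echocardiography datasets.

A dataset is one row per ECG: metadata (record id, patient id, paced-rhythm
flag, days between ECG and echo), the schema's parameter vector, and the
paired echocardiographic LVEF from which the binary label is derived
(reduced LVEF := LVEF < 40%).  Patients commonly contribute several ECGs, so
train/test splitting is done at the patient level: all records of a patient
land on one side of the split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .schema import ParameterSchema, default_schema

#: LVEF threshold (percent) below which left ventricular function is "reduced"
REDUCED_LVEF_THRESHOLD = 40.0

META_COLUMNS = ["record_id", "patient_id", "paced", "days_to_echo", "lvef"]


class SchemaError(ValueError):
    """Input table does not conform to the parameter schema."""


class SplitError(ValueError):
    """Patient-grouped split cannot be performed."""


@dataclass
class PairedDataset:
    """One row per ECG with its paired LVEF label.

    ``df`` holds the metadata columns followed by the schema parameters, in
    schema order.  ``split_tag`` records provenance ('unsplit', 'train',
    'test' or 'external').
    """

    df: pd.DataFrame
    schema: ParameterSchema = field(default_factory=default_schema)
    split_tag: str = "unsplit"

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.df.columns]
        missing += [c for c in self.schema.names if c not in self.df.columns]
        if missing:
            raise SchemaError(f"dataset is missing required columns: {missing[:8]}")
        lvef = self.df["lvef"].to_numpy(dtype=float)
        if np.isnan(lvef).any():
            raise ValueError("missing LVEF values")
        bad = (lvef < 0) | (lvef > 100)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(f"LVEF outside [0, 100] at row {i}: {lvef[i]}")
        vals = self.df[self.schema.names]
        if vals.isna().any().any():
            col = vals.columns[vals.isna().any()][0]
            row = int(vals.index[vals[col].isna()][0])
            raise ValueError(f"missing value in column {col!r} at row {row}")
        # canonical column order: metadata then schema parameters
        self.df = self.df[META_COLUMNS + self.schema.names].reset_index(drop=True)

    # ---- accessors -----------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def values(self) -> np.ndarray:
        """n x p parameter matrix aligned to the schema."""
        return self.df[self.schema.names].to_numpy(dtype=float)

    @property
    def lvef(self) -> np.ndarray:
        return self.df["lvef"].to_numpy(dtype=float)

    @property
    def reduced(self) -> np.ndarray:
        """Boolean label vector: LVEF < 40%."""
        return self.lvef < REDUCED_LVEF_THRESHOLD

    @property
    def paced(self) -> np.ndarray:
        return self.df["paced"].to_numpy(dtype=bool)

    @property
    def patient_ids(self) -> np.ndarray:
        return self.df["patient_id"].to_numpy(dtype=str)

    @property
    def record_ids(self) -> np.ndarray:
        return self.df["record_id"].to_numpy(dtype=str)

    def subset(self, index, split_tag: Optional[str] = None) -> "PairedDataset":
        return PairedDataset(
            self.df.iloc[np.asarray(index)].reset_index(drop=True),
            schema=self.schema,
            split_tag=split_tag or self.split_tag,
        )


def load_dataset(path, schema: Optional[ParameterSchema] = None,
                 impute_median: bool = False) -> PairedDataset:
    """Read a delimited parameter table into a validated :class:`PairedDataset`.

    The file must carry a header with ``record_id``, ``patient_id``, ``lvef``,
    ``paced`` and every schema parameter name; column order is irrelevant
    (loading is name-driven).  Missing values are rejected unless
    ``impute_median`` is set, in which case parameter columns are filled with
    their column median.
    """
    schema = schema or default_schema()
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    required = ["record_id", "patient_id", "lvef", "paced"]
    for col in required + schema.names:
        if col not in df.columns:
            raise SchemaError(f"input table lacks required column {col!r}")
    if "days_to_echo" not in df.columns:
        df["days_to_echo"] = 0
    for col in schema.names + ["lvef"]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        fresh_nan = coerced.isna() & df[col].notna()
        if fresh_nan.any():
            row = int(df.index[fresh_nan][0])
            raise ValueError(f"non-numeric value in column {col!r} at row {row}")
        df[col] = coerced
    if impute_median:
        for col in schema.names:
            df[col] = df[col].fillna(df[col].median())
    df["paced"] = df["paced"].astype(bool)
    return PairedDataset(df, schema=schema)


def write_dataset(ds: PairedDataset, path) -> None:
    """Write the dataset as CSV; round-trips bit-exactly through load_dataset."""
    df = ds.df.copy()
    df["paced"] = df["paced"].astype(bool)
    df.to_csv(path, index=False, float_format="%.17g")


def split_by_patient(ds: PairedDataset, test_fraction: float, seed: int
                     ) -> tuple[PairedDataset, PairedDataset]:
    """Patient-grouped random split into (train, test).

    Patients are shuffled with the given seed and assigned to the test side
    until the running record count reaches ``test_fraction`` of all records;
    every patient's records land entirely on one side.  Deterministic in
    ``seed``.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    patients = pd.unique(ds.df["patient_id"])
    if len(patients) < 2:
        raise SplitError("need at least 2 patients to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    counts = ds.df["patient_id"].value_counts()
    target = test_fraction * len(ds)
    test_patients, acc = set(), 0
    for i in order:
        pid = patients[i]
        c = int(counts[pid])
        # take the patient if it brings us closer to the target count
        if abs(acc + c - target) <= abs(acc - target) or acc == 0:
            test_patients.add(pid)
            acc += c
        if acc >= target:
            break
    in_test = ds.df["patient_id"].isin(test_patients).to_numpy()
    if in_test.all() or not in_test.any():
        raise SplitError("degenerate split; adjust test_fraction")
    train = ds.subset(np.flatnonzero(~in_test), split_tag="train")
    test = ds.subset(np.flatnonzero(in_test), split_tag="test")
    return train, test


def prevalence(ds: PairedDataset) -> float:
    """Percentage of records with reduced LVEF, to one decimal."""
    if len(ds) == 0:
        raise ValueError("empty dataset")
    return round(100.0 * float(np.mean(ds.reduced)), 1)


def record_fraction(n_part: int, n_total: int) -> float:
    """Percentage of records in a split, to one decimal (e.g. 80.6)."""
    if n_total <= 0 or not 0 <= n_part <= n_total:
        raise ValueError("invalid counts")
    return round(100.0 * n_part / n_total, 1)
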