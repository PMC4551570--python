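"""Long-format measurement tables for two-method agreement studies.

The universal input is a table with one row per measurement: a subject
identifier, a method code (1 = reference/established method, 2 = new
method), a positive replicate (session) index, and a real-valued
measurement in data units.  Replicate counts may differ across subjects
and across methods within a subject; the same replicate index on both
methods denotes the paired session, and a session present for only one
method is simply a missing cell (no sentinel rows).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("subject", "method", "replicate", "value")


class MeasurementTableError(ValueError):
    """Raised when an input table violates the measurement-table contract."""


@dataclass(frozen=True)
class MeasurementTable:
    """Validated long-format replicated two-method measurements.

    Parameters
    ----------
    frame : pandas.DataFrame
        Columns ``subject`` (opaque label), ``method`` (int, 1 or 2),
        ``replicate`` (positive int), ``value`` (float).

    Invariants enforced at construction:

    * at most one record per (subject, method, replicate) triple;
    * at least two distinct subjects;
    * each method has at least one record overall;
    * at least one subject has >= 2 replicates for at least one method
      (otherwise within- and between-subject variance are not separable).
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise MeasurementTableError(f"missing required columns: {missing}")
        df = df.loc[:, list(REQUIRED_COLUMNS)].copy()
        df["method"] = df["method"].astype(int)
        df["replicate"] = df["replicate"].astype(int)
        df["value"] = df["value"].astype(float)

        bad_methods = sorted(set(df["method"]) - {1, 2})
        if bad_methods:
            raise MeasurementTableError(
                f"method codes must be 1 or 2, got {bad_methods}"
            )
        if (df["replicate"] < 1).any():
            raise MeasurementTableError("replicate indices must be positive")
        if not np.isfinite(df["value"]).all():
            raise MeasurementTableError("values must be finite")

        dup = df.duplicated(subset=["subject", "method", "replicate"], keep=False)
        if dup.any():
            offenders = (
                df.loc[dup, ["subject", "method", "replicate"]]
                .drop_duplicates()
                .itertuples(index=False, name=None)
            )
            raise MeasurementTableError(
                "duplicate (subject, method, replicate) triples: "
                + ", ".join(map(str, offenders))
            )

        if df["subject"].nunique() < 2:
            raise MeasurementTableError("at least two distinct subjects required")
        present = set(df["method"].unique())
        for m in (1, 2):
            if m not in present:
                raise MeasurementTableError(
                    f"method {m} has no records; both methods must be observed"
                )
        reps = df.groupby(["subject", "method"], sort=False)["replicate"].nunique()
        if (reps < 2).all():
            raise MeasurementTableError(
                "no subject has >= 2 replicates on any method; "
                "within- and between-subject variability are not separable"
            )

        df = df.sort_values(["subject", "replicate", "method"], kind="mergesort")
        object.__setattr__(self, "frame", df.reset_index(drop=True))

    # -- constructors ------------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "MeasurementTable":
        return cls(df)

    @classmethod
    def from_records(cls, records) -> "MeasurementTable":
        """Build from an iterable of (subject, method, replicate, value)."""
        return cls(pd.DataFrame(records, columns=list(REQUIRED_COLUMNS)))

    # -- accessors ---------------------------------------------------

    @property
    def subjects(self) -> list:
        return list(dict.fromkeys(self.frame["subject"]))

    @property
    def n_subjects(self) -> int:
        return self.frame["subject"].nunique()

    @property
    def n_records(self) -> int:
        return len(self.frame)

    def method_values(self, method: int) -> np.ndarray:
        return self.frame.loc[self.frame["method"] == method, "value"].to_numpy()

    def swap_methods(self) -> "MeasurementTable":
        """Relabel method 1 <-> 2 (useful for symmetry checks)."""
        df = self.frame.copy()
        df["method"] = 3 - df["method"]
        return MeasurementTable(df)

    def to_csv(self, path, labels: dict[int, str] | None = None) -> None:
        df = self.frame.copy()
        if labels:
            df["method"] = df["method"].map(labels)
        df.to_csv(path, index=False)


def read_long_csv(path, mapping: dict[str, int] | None = None) -> MeasurementTable:
    """Read a long-format CSV with header ``subject,method,replicate,value``.

    Parameters
    ----------
    path : str or Path
        CSV file, comma-separated, dot decimal, UTF-8.
    mapping : dict, optional
        Maps method label strings to {1, 2} (the label mapped to 1 is the
        reference method).  If omitted, the method column must already
        contain 1/2 codes.
    """
    header = pd.read_csv(path, nrows=0)
    if list(header.columns) != list(REQUIRED_COLUMNS):
        raise MeasurementTableError(
            f"header must be exactly {','.join(REQUIRED_COLUMNS)}, "
            f"got {','.join(map(str, header.columns))}"
        )
    df = pd.read_csv(path, dtype={"subject": str, "method": str})

    bad = pd.to_numeric(df["value"], errors="coerce").isna() & df["value"].notna()
    if bad.any() or df["value"].isna().any():
        lines = (df.index[bad | df["value"].isna()] + 2).tolist()  # 1-based + header
        raise MeasurementTableError(f"non-numeric value on line(s) {lines}")
    df["value"] = pd.to_numeric(df["value"])

    labels = df["method"].astype(str)
    if mapping is None:
        if not labels.isin({"1", "2"}).all():
            unknown = sorted(set(labels) - {"1", "2"})
            raise MeasurementTableError(
                f"unknown method label(s) {unknown}; provide a label mapping"
            )
        df["method"] = labels.astype(int)
    else:
        unknown = sorted(set(labels) - set(mapping))
        if unknown:
            raise MeasurementTableError(
                f"unknown method label(s) {unknown}; configured mapping: {mapping}"
            )
        if sorted(mapping.values()) != [1, 2]:
            raise MeasurementTableError(
                f"method mapping must assign codes 1 and 2 exactly once: {mapping}"
            )
        df["method"] = labels.map(mapping)

    return MeasurementTable(df)
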