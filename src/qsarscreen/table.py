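"""The descriptor table — the pipeline's universal data currency.

A :class:`DescriptorTable` is a compound-by-descriptor numeric matrix with
an optional activity vector (pIC50, i.e. -log10 IC50).  It round-trips to
CSV with the layout ``compound_id, <descriptor columns...>, activity`` and
converts to/from :class:`pandas.DataFrame` for interactive work.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

ACTIVITY_COLUMN = "pIC50"


@dataclass
class DescriptorTable:
    """Compound-by-descriptor matrix with optional activity.

    Parameters
    ----------
    compound_ids
        Unique text identifiers, one per row.
    descriptor_names
        Unique column names, one per descriptor.
    values
        ``(n_compounds, n_descriptors)`` float matrix; must be finite.
    activity
        Optional length-``n_compounds`` pIC50 vector.
    """

    compound_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray
    activity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ConfigurationError("values must be a 2-D matrix")
        n, p = self.values.shape
        self.compound_ids = [str(c) for c in self.compound_ids]
        self.descriptor_names = [str(d) for d in self.descriptor_names]
        if len(self.compound_ids) != n:
            raise ConfigurationError(
                f"{len(self.compound_ids)} compound ids for {n} rows"
            )
        if len(self.descriptor_names) != p:
            raise ConfigurationError(
                f"{len(self.descriptor_names)} descriptor names for {p} columns"
            )
        if len(set(self.compound_ids)) != n:
            raise ConfigurationError("duplicate compound ids")
        if len(set(self.descriptor_names)) != p:
            raise ConfigurationError("duplicate descriptor names")
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("descriptor values must be finite")
        if self.activity is not None:
            self.activity = np.asarray(self.activity, dtype=float)
            if self.activity.shape != (n,):
                raise ConfigurationError(
                    f"activity length {self.activity.shape} does not match {n} rows"
                )
            if not np.all(np.isfinite(self.activity)):
                raise ConfigurationError("activity values must be finite")

    # ------------------------------------------------------------------
    # basic accessors
    # ------------------------------------------------------------------
    @property
    def n_compounds(self) -> int:
        return self.values.shape[0]

    @property
    def n_descriptors(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        """Return one descriptor column by name."""
        try:
            j = self.descriptor_names.index(name)
        except ValueError:
            raise ConfigurationError(f"no descriptor column named {name!r}") from None
        return self.values[:, j]

    def matrix(self, names: Sequence[str]) -> np.ndarray:
        """Return the sub-matrix for ``names`` in the given order."""
        idx = []
        for name in names:
            if name not in self.descriptor_names:
                raise ConfigurationError(f"no descriptor column named {name!r}")
            idx.append(self.descriptor_names.index(name))
        return self.values[:, idx]

    def select_columns(self, names: Sequence[str]) -> "DescriptorTable":
        """New table restricted to ``names`` (activity carried along)."""
        return DescriptorTable(
            compound_ids=list(self.compound_ids),
            descriptor_names=list(names),
            values=self.matrix(names).copy(),
            activity=None if self.activity is None else self.activity.copy(),
        )

    def select_rows(self, indices: Sequence[int]) -> "DescriptorTable":
        """New table restricted to the given row indices, in that order."""
        idx = list(indices)
        return DescriptorTable(
            compound_ids=[self.compound_ids[i] for i in idx],
            descriptor_names=list(self.descriptor_names),
            values=self.values[idx, :].copy(),
            activity=None if self.activity is None else self.activity[idx].copy(),
        )

    def drop_columns(self, names: Sequence[str]) -> "DescriptorTable":
        drop = set(names)
        keep = [d for d in self.descriptor_names if d not in drop]
        return self.select_columns(keep)

    # ------------------------------------------------------------------
    # pandas / CSV interop
    # ------------------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.descriptor_names)
        df.insert(0, "compound_id", self.compound_ids)
        if self.activity is not None:
            df[ACTIVITY_COLUMN] = self.activity
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DescriptorTable":
        if "compound_id" not in df.columns:
            raise ConfigurationError("expected a 'compound_id' column")
        activity = None
        cols = [c for c in df.columns if c != "compound_id"]
        if ACTIVITY_COLUMN in cols:
            activity = df[ACTIVITY_COLUMN].to_numpy(dtype=float)
            cols = [c for c in cols if c != ACTIVITY_COLUMN]
        return cls(
            compound_ids=df["compound_id"].astype(str).tolist(),
            descriptor_names=list(cols),
            values=df[cols].to_numpy(dtype=float),
            activity=activity,
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "DescriptorTable":
        return cls.from_dataframe(pd.read_csv(path))
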