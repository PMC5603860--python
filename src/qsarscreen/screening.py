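"""Apply a fitted model to candidate compounds and rank the predictions.

Screening never silently drops candidates: every record carries its
predicted activity, leverage, and a reliability flag (leverage < h*), and
the caller decides what to do with out-of-domain predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .modeling import LinearModel
from .table import DescriptorTable
from .validation import applicability_domain

__all__ = ["ScreeningRecord", "ScreeningReport", "predict", "screen"]


@dataclass(frozen=True)
class ScreeningRecord:
    candidate_id: str
    predicted_activity: float  # pIC50
    leverage: float
    reliable: bool  # leverage < h*


@dataclass
class ScreeningReport:
    """Records sorted by descending predicted activity (ties by id)."""

    records: list[ScreeningRecord]
    model_reference: str
    h_star: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "candidate_id": [r.candidate_id for r in self.records],
                "predicted_pIC50": [r.predicted_activity for r in self.records],
                "leverage": [r.leverage for r in self.records],
                "reliable": [r.reliable for r in self.records],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def reliable_only(self) -> list[ScreeningRecord]:
        return [r for r in self.records if r.reliable]


def predict(model: LinearModel, table: DescriptorTable) -> np.ndarray:
    """Predicted activity ŷ = intercept + Σ β_j x_j for each row.

    The table must provide every model descriptor; extra columns are
    ignored.
    """
    missing = [d for d in model.descriptor_names if d not in table.descriptor_names]
    if missing:
        raise ConfigurationError(f"candidate table lacks model descriptors: {missing}")
    return model.predict_matrix(table.matrix(model.descriptor_names))


def screen(
    model: LinearModel,
    candidates: DescriptorTable,
    model_reference: str = "model",
) -> ScreeningReport:
    """Predict, attach applicability-domain flags, and rank candidates.

    One record per candidate, none dropped; ``reliable`` is True exactly
    when leverage < h* for the model's training geometry.
    """
    preds = predict(model, candidates)
    ad = applicability_domain(model, candidates)
    records = [
        ScreeningRecord(
            candidate_id=cid,
            predicted_activity=float(yhat),
            leverage=float(h),
            reliable=bool(h < ad.h_star),
        )
        for cid, yhat, h in zip(candidates.compound_ids, preds, ad.leverages)
    ]
    records.sort(key=lambda r: (-r.predicted_activity, r.candidate_id))
    return ScreeningReport(records=records, model_reference=model_reference, h_star=ad.h_star)
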