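"""External predictivity, Y-randomization and applicability domain.

External validation follows the Golbraikh–Tropsha decision rules on a
held-out prediction set: squared correlation R²pred between observed and
predicted activities, the through-origin regressions in both directions
(R0², R′0² and slopes k, k′), and Roy's rm² = R²pred·(1 − sqrt(|R²pred −
R0²|)).  A model passes when

    (i)   Q² (training LOO) > 0.5
    (ii)  R²pred > 0.6
    (iii) |(R²pred − R0²)/R²pred| < 0.1 or the R′0² analogue
    (iv)  0.85 ≤ k ≤ 1.15 or 0.85 ≤ k′ ≤ 1.15
    (v)   rm² > 0.5

Y-randomization refits models on permuted activity vectors to rule out
chance correlation, and the applicability domain is the leverage region
h < h* = 3(k+1)/n around the training data (Williams-plot coordinates:
leverage vs standardized residual).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ModelingError, ValidationError
from .modeling import (
    GAConfig,
    LinearModel,
    StepwiseConfig,
    fit_mlr,
    ga_select,
    outlier_flags,
    standardized_residuals,
    stepwise_select,
)
from .table import DescriptorTable

__all__ = [
    "ExternalValidationReport",
    "YRandomizationResult",
    "ADReport",
    "external_validate",
    "tropsha_check",
    "y_randomize",
    "applicability_domain",
    "leverage_threshold",
    "williams_plot_data",
]


@dataclass
class ExternalValidationReport:
    """Golbraikh–Tropsha statistics for one prediction set."""

    r2_pred: float
    q2_ext: float
    r0sq: float
    r0sq_prime: float
    k: float
    k_prime: float
    rm2: float
    rm2_prime: float
    rel_diff_r0: float
    rel_diff_r0_prime: float
    passes: dict[str, bool]
    overall_pass: bool

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


@dataclass
class YRandomizationResult:
    """R²/Q² of models refit on shuffled activities, vs the original."""

    n_repetitions: int
    shuffled_r2: np.ndarray
    shuffled_q2: np.ndarray
    original_r2: float
    original_q2: float


@dataclass
class ADReport:
    """Leverage-based applicability domain for a set of compounds.

    ``inside_flags`` marks compounds with leverage strictly below
    h* = 3(k+1)/n; boundary equality counts as outside.
    ``residual_flags`` (training tables only) marks |standardized
    residual| > 2.5; ``None`` entries mean not applicable.
    """

    compound_ids: list[str]
    leverages: np.ndarray
    h_star: float
    inside_flags: np.ndarray
    standardized_residuals: np.ndarray | None = None
    residual_flags: np.ndarray | None = None


def _through_origin(y: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Slope and R0² of the no-intercept regression of y on x.

    R0² is referenced to the mean of y: R0² = 1 − Σ(y − kx)²/Σ(y − ȳ)².
    """
    k = float((y @ x) / (x @ x))
    ss_res = float(((y - k * x) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return k, 1.0 - ss_res / ss_tot


def external_validate(
    observed: np.ndarray, predicted: np.ndarray
) -> ExternalValidationReport:
    """Compute the external-set predictivity bundle.

    ``r2_pred`` is the squared Pearson correlation between predicted and
    observed activities; ``q2_ext`` (1 − SSres/SStot) is reported as an
    auxiliary diagnostic but takes no part in the pass rules.  rm² uses
    the absolute difference |R²pred − R0²| under the square root.
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or y.size < 3:
        raise ConfigurationError("need equal-length 1-D vectors with >= 3 entries")
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        raise ValidationError("observed or predicted activities have zero variance")

    r2_pred = float(np.corrcoef(y, yhat)[0, 1] ** 2)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    q2_ext = 1.0 - float(((y - yhat) ** 2).sum()) / ss_tot

    k, r0sq = _through_origin(y, yhat)          # observed on predicted
    k_prime, r0sq_prime = _through_origin(yhat, y)  # predicted on observed

    rm2 = r2_pred * (1.0 - np.sqrt(abs(r2_pred - r0sq)))
    rm2_prime = r2_pred * (1.0 - np.sqrt(abs(r2_pred - r0sq_prime)))
    rel_diff_r0 = (r2_pred - r0sq) / r2_pred
    rel_diff_r0_prime = (r2_pred - r0sq_prime) / r2_pred

    passes = {
        "r2_pred_gt_0.6": bool(r2_pred > 0.6),
        "r0_close": bool(abs(rel_diff_r0) < 0.1 or abs(rel_diff_r0_prime) < 0.1),
        "slope_in_band": bool(0.85 <= k <= 1.15 or 0.85 <= k_prime <= 1.15),
        "rm2_gt_0.5": bool(rm2 > 0.5),
    }
    return ExternalValidationReport(
        r2_pred=r2_pred,
        q2_ext=q2_ext,
        r0sq=r0sq,
        r0sq_prime=r0sq_prime,
        k=k,
        k_prime=k_prime,
        rm2=float(rm2),
        rm2_prime=float(rm2_prime),
        rel_diff_r0=float(rel_diff_r0),
        rel_diff_r0_prime=float(rel_diff_r0_prime),
        passes=passes,
        overall_pass=all(passes.values()),
    )


def tropsha_check(q2_train: float, report: ExternalValidationReport) -> ExternalValidationReport:
    """Add the internal rule Q² > 0.5 and refresh the overall verdict.

    Returns a new report whose ``passes`` include all five rules; the
    R0²/slope rules keep their either-variant (disjunctive) reading.
    """
    passes = dict(report.passes)
    passes["q2_gt_0.5"] = bool(q2_train > 0.5)
    return ExternalValidationReport(
        **{
            **{f.name: getattr(report, f.name) for f in report.__dataclass_fields__.values()},
            "passes": passes,
            "overall_pass": all(passes.values()),
        }
    )


def y_randomize(
    table: DescriptorTable,
    selection: str = "refit_fixed",
    n_repetitions: int = 20,
    seed: int = 0,
    descriptor_names: list[str] | None = None,
    stepwise_config: StepwiseConfig | None = None,
    ga_config: GAConfig | None = None,
) -> YRandomizationResult:
    """Refit models on seeded permutations of the activity vector.

    ``selection`` chooses how each scrambled model is built:

    * ``refit_fixed`` — OLS on a fixed descriptor set
      (``descriptor_names`` required); fast, tests the fit only.
    * ``rerun_stepwise`` / ``rerun_ga`` — rerun the full selection
      procedure per permutation, the stricter reading of scrambling.

    A sound model should leave shuffled R² low and shuffled Q² mostly
    negative.
    """
    if table.activity is None:
        raise ConfigurationError("Y-randomization requires an activity column")
    if n_repetitions < 1:
        raise ConfigurationError("n_repetitions must be >= 1")

    def build(t: DescriptorTable, rep: int) -> LinearModel:
        if selection == "refit_fixed":
            if descriptor_names is None:
                raise ConfigurationError("refit_fixed needs descriptor_names")
            return fit_mlr(t, descriptor_names)
        if selection == "rerun_stepwise":
            return stepwise_select(t, stepwise_config or StepwiseConfig())
        if selection == "rerun_ga":
            base = ga_config or GAConfig()
            cfg = GAConfig(**{**asdict(base), "seed": (base.seed + 7919 * rep) % (2**31)})
            return ga_select(t, cfg)[0]
        raise ConfigurationError(
            f"unknown selection mode {selection!r}; expected refit_fixed, "
            "rerun_stepwise or rerun_ga"
        )

    original = build(table, 0)
    rng = np.random.default_rng(seed)
    r2s = np.empty(n_repetitions)
    q2s = np.empty(n_repetitions)
    for rep in range(n_repetitions):
        perm = rng.permutation(table.n_compounds)
        shuffled = DescriptorTable(
            compound_ids=list(table.compound_ids),
            descriptor_names=list(table.descriptor_names),
            values=table.values,
            activity=table.activity[perm],
        )
        model = build(shuffled, rep + 1)
        r2s[rep] = model.fit_stats.r2
        q2s[rep] = model.fit_stats.q2_loo
    return YRandomizationResult(
        n_repetitions=n_repetitions,
        shuffled_r2=r2s,
        shuffled_q2=q2s,
        original_r2=original.fit_stats.r2,
        original_q2=original.fit_stats.q2_loo,
    )


def leverage_threshold(k: int, n: int) -> float:
    """Warning leverage h* = 3(k+1)/n for k descriptors and n training compounds."""
    return 3.0 * (k + 1) / n


def applicability_domain(model: LinearModel, table: DescriptorTable) -> ADReport:
    """Leverage of each compound relative to the model's training design.

    h_i = x_i (XᵀX)⁻¹ x_iᵀ with intercept-augmented rows and X the stored
    training design.  Compounds with h < h* = 3(k+1)/n lie inside the
    applicability domain.  When the table *is* the training set (same
    compound ids), standardized residuals and outlier flags are attached.
    """
    Xt = model.design_matrix(model.training_design)
    xtx = Xt.T @ Xt
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError as exc:
        raise ModelingError("training design XᵀX is singular") from exc
    Xq = model.design_matrix(table.matrix(model.descriptor_names))
    leverages = np.einsum("ij,jk,ik->i", Xq, xtx_inv, Xq)
    h_star = leverage_threshold(model.k, model.n_train)
    inside = leverages < h_star

    residuals = flags = None
    if list(table.compound_ids) == list(model.training_ids):
        residuals = standardized_residuals(model, table if table.activity is not None else None)
        flags = outlier_flags(residuals)
    return ADReport(
        compound_ids=list(table.compound_ids),
        leverages=leverages,
        h_star=h_star,
        inside_flags=inside,
        standardized_residuals=residuals,
        residual_flags=flags,
    )


def williams_plot_data(report: ADReport) -> pd.DataFrame:
    """Williams-plot coordinates (leverage vs standardized residual) as a frame."""
    df = pd.DataFrame(
        {
            "compound_id": report.compound_ids,
            "leverage": report.leverages,
            "inside_domain": report.inside_flags,
        }
    )
    if report.standardized_residuals is not None:
        df["standardized_residual"] = report.standardized_residuals
        df["residual_outlier"] = report.residual_flags
    df.attrs["h_star"] = report.h_star
    return df


def williams_plot(report: ADReport, path: str | Path) -> None:
    """Render the Williams plot (h* and ±2.5 guides) to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    resid = (
        report.standardized_residuals
        if report.standardized_residuals is not None
        else np.zeros(len(report.leverages))
    )
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(report.leverages, resid, s=18)
    ax.axvline(report.h_star, color="crimson", ls="--", label=f"h* = {report.h_star:.2f}")
    for guide in (-2.5, 2.5):
        ax.axhline(guide, color="grey", ls=":")
    ax.set_xlabel("leverage h")
    ax.set_ylabel("standardized residual")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
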