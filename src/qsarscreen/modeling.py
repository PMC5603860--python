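"""MLR fitting, leave-one-out cross-validation, and descriptor selection.

The modelling core is ordinary least squares with an intercept.  Internal
quality is summarized by R², adjusted R², the regression F statistic, the
standard error of regression, and the leave-one-out statistics Q², RMScv
and PRESS.  LOO quantities use the hat-matrix shortcut

    e_(i) = e_i / (1 − h_ii),

which reproduces n explicit refits exactly for OLS.

Two descriptor-selection strategies are provided: classical stepwise
regression driven by partial-F probabilities, and a genetic algorithm
over descriptor-inclusion bitstrings whose fitness is the LOO RMScv of
the encoded subset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError, ModelingError
from .table import DescriptorTable

__all__ = [
    "FitStats",
    "LinearModel",
    "StepwiseConfig",
    "GAConfig",
    "fit_mlr",
    "loo_cv",
    "stepwise_select",
    "ga_select",
    "vif",
    "standardized_residuals",
    "outlier_flags",
    "OUTLIER_THRESHOLD",
]

#: |standardized residual| above which a training compound is flagged
OUTLIER_THRESHOLD = 2.5


@dataclass
class FitStats:
    """Internal fit statistics of one OLS model."""

    r2: float
    r2_adj: float
    f_stat: float
    se: float
    q2_loo: float
    rmscv: float
    press: float


@dataclass
class LinearModel:
    """A fitted MLR model with its training snapshot.

    The snapshot (``training_design``, ``training_activity``) is what
    leverage-based applicability-domain assessment and residual
    diagnostics recompute from; it stores the *unaugmented* descriptor
    columns in ``descriptor_names`` order.
    """

    descriptor_names: list[str]
    intercept: float
    coefficients: np.ndarray
    coefficient_ses: np.ndarray
    intercept_se: float
    training_ids: list[str]
    fit_stats: FitStats
    training_design: np.ndarray
    training_activity: np.ndarray

    @property
    def k(self) -> int:
        """Number of descriptors in the model."""
        return len(self.descriptor_names)

    @property
    def n_train(self) -> int:
        return len(self.training_ids)

    def design_matrix(self, X: np.ndarray) -> np.ndarray:
        return np.column_stack([np.ones(X.shape[0]), X])

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X, dtype=float) @ self.coefficients

    def equation(self, digits: int = 3) -> str:
        """Human-readable regression equation with ± standard errors."""
        terms = [f"{self.intercept:.{digits}f} (± {self.intercept_se:.{digits}f})"]
        for name, b, se in zip(self.descriptor_names, self.coefficients, self.coefficient_ses):
            sign = "+" if b >= 0 else "−"
            terms.append(f"{sign} {abs(b):.{digits}f} (± {se:.{digits}f}) {name}")
        return "pIC50 = " + " ".join(terms)

    # ------------------------------------------------------------------
    # JSON round trip
    # ------------------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "descriptor_names": self.descriptor_names,
            "intercept": self.intercept,
            "coefficients": self.coefficients.tolist(),
            "coefficient_ses": self.coefficient_ses.tolist(),
            "intercept_se": self.intercept_se,
            "training_ids": self.training_ids,
            "fit_stats": asdict(self.fit_stats),
            "training_design": self.training_design.tolist(),
            "training_activity": self.training_activity.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "LinearModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            descriptor_names=payload["descriptor_names"],
            intercept=payload["intercept"],
            coefficients=np.asarray(payload["coefficients"], dtype=float),
            coefficient_ses=np.asarray(payload["coefficient_ses"], dtype=float),
            intercept_se=payload["intercept_se"],
            training_ids=payload["training_ids"],
            fit_stats=FitStats(**payload["fit_stats"]),
            training_design=np.asarray(payload["training_design"], dtype=float),
            training_activity=np.asarray(payload["training_activity"], dtype=float),
        )


@dataclass(frozen=True)
class StepwiseConfig:
    """Stepwise MLR stepping criteria (partial-F probabilities)."""

    p_enter: float = 0.05
    p_remove: float = 0.10
    max_steps: int = 100

    def __post_init__(self) -> None:
        if not 0 < self.p_enter <= self.p_remove < 1:
            raise ConfigurationError("require 0 < p_enter <= p_remove < 1")


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings for descriptor-subset search.

    Crossover probability ramps linearly ``crossover_rate_start`` →
    ``crossover_rate_end`` across generations and per-bit mutation
    ``mutation_rate_start`` → ``mutation_rate_end``; by default crossover
    starts high (0.9 → 0.6) while mutation rises (0 → 0.01) to fight
    premature convergence late in the run.
    """

    population_size: int = 100
    max_generations: int = 200
    mutation_rate_start: float = 0.0
    mutation_rate_end: float = 0.01
    crossover_rate_start: float = 0.9
    crossover_rate_end: float = 0.6
    convergence_fraction: float = 0.9
    max_descriptors: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (
            self.mutation_rate_start,
            self.mutation_rate_end,
            self.crossover_rate_start,
            self.crossover_rate_end,
        ):
            if not 0 <= rate <= 1:
                raise ConfigurationError("GA rates must lie in [0, 1]")
        if not 0 < self.convergence_fraction <= 1:
            raise ConfigurationError("convergence_fraction must lie in (0, 1]")
        if self.population_size < 2:
            raise ConfigurationError("population_size must be >= 2")


# ----------------------------------------------------------------------
# OLS core
# ----------------------------------------------------------------------

def _ols(X: np.ndarray, y: np.ndarray):
    """Least squares on an augmented design via QR.

    Returns (beta, residuals, hat_diag, XtX_inv).
    """
    n, m = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < m:
        raise ModelingError(_rank_message(X))
    Q, R = np.linalg.qr(X)
    beta = np.linalg.solve(R, Q.T @ y)
    resid = y - X @ beta
    hat_diag = (Q**2).sum(axis=1)
    Rinv = np.linalg.inv(R)
    xtx_inv = Rinv @ Rinv.T
    return beta, resid, hat_diag, xtx_inv


def _rank_message(X: np.ndarray) -> str:
    """Name linearly dependent columns via pivoted QR."""
    from scipy.linalg import qr as scipy_qr

    _, R, piv = scipy_qr(X, pivoting=True, mode="economic")
    rank = np.linalg.matrix_rank(X)
    dependent = sorted(int(j) for j in piv[rank:])
    return (
        "design matrix is rank deficient; linearly dependent design "
        f"columns (0 = intercept): {dependent}"
    )


def fit_mlr(table: DescriptorTable, names: Sequence[str]) -> LinearModel:
    """Ordinary least squares of activity on the named descriptors.

    Populates the full internal statistics bundle, including the LOO
    quantities Q², RMScv and PRESS.  ``names`` may be empty, giving the
    intercept-only model.
    """
    if table.activity is None:
        raise ConfigurationError("fit_mlr requires an activity column")
    names = list(names)
    n = table.n_compounds
    k = len(names)
    if n <= k + 1:
        raise ConfigurationError(
            f"need n > k+1 observations (n={n}, k={k}) to fit with an intercept"
        )
    Xd = table.matrix(names)
    y = table.activity
    X = np.column_stack([np.ones(n), Xd])
    beta, resid, hat_diag, xtx_inv = _ols(X, y)

    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    dof = n - k - 1
    mse = ss_res / dof
    se = float(np.sqrt(mse))
    ses = np.sqrt(mse * np.diag(xtx_inv))

    if ss_tot > 0:
        r2 = 1.0 - ss_res / ss_tot
        r2_adj = 1.0 - (1.0 - r2) * (n - 1) / dof
        f_stat = ((ss_tot - ss_res) / k) / mse if k > 0 else 0.0
    else:  # constant activity: variance-explained statistics are undefined
        r2 = r2_adj = f_stat = 0.0

    q2, rmscv, press = _loo_from_fit(y, resid, hat_diag, ss_tot)

    return LinearModel(
        descriptor_names=names,
        intercept=float(beta[0]),
        coefficients=beta[1:].copy(),
        coefficient_ses=ses[1:].copy(),
        intercept_se=float(ses[0]),
        training_ids=list(table.compound_ids),
        fit_stats=FitStats(
            r2=r2, r2_adj=r2_adj, f_stat=f_stat, se=se,
            q2_loo=q2, rmscv=rmscv, press=press,
        ),
        training_design=Xd.copy(),
        training_activity=y.copy(),
    )


def _loo_from_fit(y, resid, hat_diag, ss_tot):
    if np.any(hat_diag >= 1.0 - 1e-12):
        raise ModelingError(
            "leave-one-out is degenerate: a training compound has leverage 1"
        )
    loo_resid = resid / (1.0 - hat_diag)
    press = float(loo_resid @ loo_resid)
    q2 = 1.0 - press / ss_tot if ss_tot > 0 else 0.0
    rmscv = float(np.sqrt(press / len(y)))
    return q2, rmscv, press


def loo_cv(table: DescriptorTable, names: Sequence[str]) -> tuple[float, float, float]:
    """Leave-one-out statistics ``(Q², RMScv, PRESS)`` for one subset.

    PRESS = Σ (y_i − ŷ_(−i),i)² computed with the hat-matrix shortcut;
    Q² = 1 − PRESS/SStot; RMScv = sqrt(PRESS/n).
    """
    model = fit_mlr(table, names)
    s = model.fit_stats
    return s.q2_loo, s.rmscv, s.press


# ----------------------------------------------------------------------
# stepwise selection
# ----------------------------------------------------------------------

def _partial_f_pvalues(table, included, candidates):
    """p-value of the partial F test for adding each candidate alone."""
    out = {}
    for cand in candidates:
        try:
            model = fit_mlr(table, included + [cand])
        except ModelingError:
            continue  # candidate collinear with current model
        n, k = table.n_compounds, len(included) + 1
        b = model.coefficients[-1]
        se_b = model.coefficient_ses[-1]
        if se_b == 0:
            out[cand] = 0.0
            continue
        f_val = (b / se_b) ** 2
        out[cand] = float(stats.f.sf(f_val, 1, n - k - 1))
    return out


def stepwise_select(
    table: DescriptorTable, config: StepwiseConfig = StepwiseConfig()
) -> LinearModel:
    """Forward-stepping MLR with backward elimination.

    Each cycle adds the candidate with the smallest partial-F p-value if
    it is below ``p_enter``, then removes included descriptors whose
    p-value exceeds ``p_remove``, until neither move applies or
    ``max_steps`` cycles have run.  Returns the OLS fit on the final set
    (intercept-only when nothing qualifies).
    """
    if table.activity is None:
        raise ConfigurationError("stepwise selection requires an activity column")
    if table.n_descriptors < 1:
        raise ConfigurationError("no candidate descriptors")
    included: list[str] = []
    for _ in range(config.max_steps):
        changed = False
        candidates = [d for d in table.descriptor_names if d not in included]
        # forward: only if another descriptor still fits the sample size
        if candidates and table.n_compounds > len(included) + 2:
            pvals = _partial_f_pvalues(table, included, candidates)
            if pvals:
                best = min(pvals, key=lambda c: (pvals[c], table.descriptor_names.index(c)))
                if pvals[best] < config.p_enter:
                    included.append(best)
                    changed = True
        # backward: drop the worst included descriptor above p_remove
        if included:
            model = fit_mlr(table, included)
            n, k = table.n_compounds, len(included)
            with np.errstate(divide="ignore"):
                t2 = (model.coefficients / model.coefficient_ses) ** 2
            pv = stats.f.sf(t2, 1, n - k - 1)
            worst = int(np.argmax(pv))
            if pv[worst] > config.p_remove:
                included.pop(worst)
                changed = True
        if not changed:
            break
    return fit_mlr(table, included)


# ----------------------------------------------------------------------
# genetic-algorithm selection
# ----------------------------------------------------------------------

def _subset_rmscv(table, names_arr, bits, max_desc, cache):
    """LOO RMScv of the subset encoded by ``bits``; cached by index set.

    Chromosomes selecting zero or more than ``max_desc`` descriptors get
    infinite fitness and never enter the model pool.
    """
    key = bits.tobytes()
    if key in cache:
        return cache[key]
    idx = np.flatnonzero(bits)
    if not 1 <= len(idx) <= max_desc:
        cache[key] = np.inf
        return np.inf
    try:
        _, rmscv, _ = loo_cv(table, [names_arr[j] for j in idx])
    except (ModelingError, ConfigurationError):
        rmscv = np.inf
    cache[key] = rmscv
    return rmscv


def ga_select(
    table: DescriptorTable, config: GAConfig = GAConfig()
) -> tuple[LinearModel, list[float]]:
    """Genetic-algorithm descriptor-subset search with LOO-RMScv fitness.

    Chromosomes are descriptor-inclusion bitstrings; fitness is the LOO
    RMScv of the encoded subset (lower is better), with chromosomes
    selecting zero or more than ``max_descriptors`` descriptors assigned
    infinite fitness.  Selection is a size-2 tournament, crossover is
    uniform, elitism keeps the single best chromosome, and the run stops
    when ``convergence_fraction`` of the population shares the best
    fitness or after ``max_generations``.  Fully deterministic for a
    fixed ``config.seed``.

    Returns the refitted best model and the best-fitness trajectory.
    """
    if table.activity is None:
        raise ConfigurationError("GA selection requires an activity column")
    rng = np.random.default_rng(config.seed)
    p = table.n_descriptors
    n = table.n_compounds
    max_desc = config.max_descriptors if config.max_descriptors is not None else max(1, n // 4)
    max_desc = min(max_desc, p, n - 2)
    names_arr = list(table.descriptor_names)
    pop_size = config.population_size
    cache: dict[bytes, float] = {}

    # initial population: random subsets of random size in [1, max_desc]
    population = np.zeros((pop_size, p), dtype=np.uint8)
    for c in range(pop_size):
        size = int(rng.integers(1, max_desc + 1))
        population[c, rng.choice(p, size=size, replace=False)] = 1

    def fitness_of(pop):
        return np.array(
            [_subset_rmscv(table, names_arr, pop[c], max_desc, cache) for c in range(len(pop))]
        )

    history: list[float] = []
    fitness = fitness_of(population)
    for gen in range(config.max_generations):
        frac = gen / max(config.max_generations - 1, 1)
        p_cross = config.crossover_rate_start + frac * (
            config.crossover_rate_end - config.crossover_rate_start
        )
        p_mut = config.mutation_rate_start + frac * (
            config.mutation_rate_end - config.mutation_rate_start
        )

        best_idx = int(np.argmin(fitness))
        best_fit = fitness[best_idx]
        history.append(float(best_fit))
        if np.isfinite(best_fit):
            share = np.mean(np.abs(fitness - best_fit) <= 1e-12)
            if share >= config.convergence_fraction:
                break

        # size-2 tournaments pick each parent
        def tournament():
            a, b = rng.integers(0, pop_size, size=2)
            return a if fitness[a] <= fitness[b] else b

        children = [population[best_idx].copy()]  # elitism of 1
        while len(children) < pop_size:
            pa = population[tournament()].copy()
            pb = population[tournament()].copy()
            if rng.random() < p_cross:
                mask = rng.random(p) < 0.5
                pa[mask], pb[mask] = pb[mask], pa[mask].copy()
            for child in (pa, pb):
                flip = rng.random(p) < p_mut
                child[flip] ^= 1
                if len(children) < pop_size:
                    children.append(child)
        population = np.array(children, dtype=np.uint8)
        fitness = fitness_of(population)

    # ensure a usable result even if the whole population went invalid
    best_idx = int(np.argmin(fitness))
    if not np.isfinite(fitness[best_idx]):
        raise ModelingError("GA found no valid descriptor subset")
    best_bits = population[best_idx]
    history.append(float(fitness[best_idx]))
    best_names = [names_arr[j] for j in np.flatnonzero(best_bits)]
    return fit_mlr(table, best_names), history


# ----------------------------------------------------------------------
# diagnostics
# ----------------------------------------------------------------------

def vif(table: DescriptorTable, names: Sequence[str]) -> np.ndarray:
    """Variance inflation factors VIF_j = 1/(1 − R_j²) for each descriptor.

    R_j² comes from regressing descriptor j on the other named
    descriptors (with intercept).  Perfect collinearity yields ``inf``
    rather than an exception.
    """
    names = list(names)
    if len(names) < 2:
        raise ConfigurationError("VIF needs at least 2 descriptors")
    X = table.matrix(names)
    n = X.shape[0]
    out = np.empty(len(names))
    for j in range(len(names)):
        target = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(others, target, rcond=None)
        resid = target - others @ coef
        ss_tot = float(((target - target.mean()) ** 2).sum())
        if ss_tot == 0:
            out[j] = np.inf
            continue
        r2_j = 1.0 - float(resid @ resid) / ss_tot
        out[j] = np.inf if r2_j >= 1.0 - 1e-12 else 1.0 / (1.0 - r2_j)
    return out


def standardized_residuals(model: LinearModel, table: DescriptorTable | None = None) -> np.ndarray:
    """Internally studentized residuals r_i = e_i / (SE·sqrt(1 − h_ii)).

    Computed on the model's training snapshot by default; a table with
    the same compounds may be passed to recompute from fresh data.  A row
    with leverage 1 gets ``nan`` (undefined leave-one-out geometry).
    """
    if table is None:
        X = model.training_design
        y = model.training_activity
    else:
        if list(table.compound_ids) != list(model.training_ids):
            raise ConfigurationError("table compounds do not match the training set")
        X = table.matrix(model.descriptor_names)
        y = table.activity if table.activity is not None else model.training_activity
    Xa = model.design_matrix(X)
    _, resid, hat_diag, _ = _ols(Xa, y)
    se = model.fit_stats.se
    # exact fit: the residuals are pure roundoff, so studentizing them
    # would divide noise by noise — report zeros instead
    y_scale = max(float(np.abs(y).max()), 1.0)
    if se <= 1e-12 * y_scale:
        return np.zeros_like(resid)
    denom = se * np.sqrt(np.clip(1.0 - hat_diag, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, resid / denom, np.nan)
    return r


def outlier_flags(residuals: np.ndarray, threshold: float = OUTLIER_THRESHOLD) -> np.ndarray:
    """Strict-inequality outlier flags: |r_i| > threshold (nan counts as flagged)."""
    r = np.asarray(residuals, dtype=float)
    return np.isnan(r) | (np.abs(r) > threshold)
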