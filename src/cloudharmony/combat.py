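"""ComBat-family harmonization benchmarks.

Location/scale (L/S) batch correction: the value of feature f for sample j in
batch i is modeled as

    Y_ijf = a_f + X b_f + gamma_if + delta_if * eps_ijf

with additive (gamma) and multiplicative (delta) batch effects. Per-batch
estimates are shrunk toward cross-feature empirical-Bayes priors (normal for
gamma, inverse-gamma for delta^2) via the standard parametric iterative
conditional posterior means, then the data are corrected as

    Y*_ijf = (Y_ijf - a_f - X b_f - gamma*_if) / delta*_if + a_f + X b_f.

Variants implemented on top of the single-factor fit:

* ``ls-only`` mode — raw per-batch location/scale moments, no shrinkage;
* ReComBat — the same estimator with an L2 (ridge) penalty on the design
  coefficients, for ill-conditioned designs;
* sequential cascades over several batch factors in a caller-chosen order;
* a simplified optimal-order selector that scores every factor permutation by
  the count of residual feature-factor associations (Kruskal-Wallis) left
  after correction and keeps the order with the fewest.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_data import LesionTable

EB_TOL = 1e-6
EB_MAX_ITER = 500


class CombatFitError(ValueError):
    """Raised when the L/S model cannot be estimated on the given table."""


class CombatApplyError(ValueError):
    """Raised when a fitted model cannot be applied to a table."""


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

@dataclass
class CombatModel:
    """Fitted per-feature L/S batch parameters for one batch factor.

    gamma_star / delta_star are stored on the *standardized* scale used
    internally; :meth:`additive_effects` / :meth:`multiplicative_effects`
    report them on the original data scale.
    """

    batch_factor: str
    batches: list[str]
    batch_sizes: dict[str, int]
    grand_mean: np.ndarray            # a_f, (d,)
    pooled_sd: np.ndarray             # sigma_f, (d,)
    gamma_star: np.ndarray            # (n_batches, d), standardized scale
    delta_star: np.ndarray            # (n_batches, d), standardized scale, > 0
    mode: str                         # "eb-parametric" | "ls-only"
    ridge: float = 0.0
    eb_hyper: dict = field(default_factory=dict)
    design_columns: list[str] = field(default_factory=list)
    beta: np.ndarray | None = None    # (p, d) covariate coefficients

    def additive_effects(self) -> dict[str, np.ndarray]:
        """Per-batch additive effect gamma* on the original data scale."""
        return {b: self.gamma_star[i] * self.pooled_sd for i, b in enumerate(self.batches)}

    def multiplicative_effects(self) -> dict[str, np.ndarray]:
        """Per-batch multiplicative effect delta* on the original data scale."""
        return {b: self.delta_star[i] * self.pooled_sd for i, b in enumerate(self.batches)}

    def to_dict(self) -> dict:
        return {
            "batch_factor": self.batch_factor,
            "batches": self.batches,
            "batch_sizes": self.batch_sizes,
            "grand_mean": self.grand_mean.tolist(),
            "pooled_sd": self.pooled_sd.tolist(),
            "gamma_star": self.gamma_star.tolist(),
            "delta_star": self.delta_star.tolist(),
            "mode": self.mode,
            "ridge": self.ridge,
            "eb_hyper": {k: np.asarray(v).tolist() for k, v in self.eb_hyper.items()},
        }


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _batch_design(labels: np.ndarray, batches: list[str]) -> np.ndarray:
    return np.column_stack([(labels == b).astype(float) for b in batches])


def combat_fit(
    table: LesionTable,
    batch_factor: str,
    design: np.ndarray | None = None,
    mode: str = "eb-parametric",
    ridge: float = 0.0,
) -> CombatModel:
    """Fit the L/S model for one batch factor (``center`` or ``scanner``).

    Parameters
    ----------
    design:
        Optional (n, p) covariate matrix whose effects are preserved by the
        correction. Default: intercept only (no covariates).
    mode:
        ``eb-parametric`` shrinks per-batch moments with the parametric
        empirical-Bayes scheme; ``ls-only`` uses the raw moments.
    ridge:
        L2 penalty on the design coefficients (the ReComBat variant);
        0 reproduces plain ComBat.
    """
    if mode not in ("eb-parametric", "ls-only"):
        raise ValueError(f"unknown mode {mode!r}")
    if batch_factor not in ("center", "scanner"):
        raise ValueError(f"batch_factor must be 'center' or 'scanner', got {batch_factor!r}")
    if ridge < 0:
        raise ValueError("ridge must be >= 0")

    y = table.features
    n, d = y.shape
    labels = table.df[batch_factor].to_numpy()
    batches = sorted(set(labels))
    sizes = {b: int((labels == b).sum()) for b in batches}
    small = [b for b, k in sizes.items() if k < 2]
    if small:
        raise CombatFitError(f"batch(es) {small} have fewer than 2 samples")

    bmat = _batch_design(labels, batches)
    dmat = bmat if design is None else np.column_stack([bmat, np.asarray(design, float)])
    p_cov = 0 if design is None else np.asarray(design).shape[1]

    gram = dmat.T @ dmat
    if ridge > 0:
        gram = gram + ridge * np.eye(gram.shape[0])
    else:
        if np.linalg.matrix_rank(gram) < gram.shape[0]:
            raise CombatFitError(
                "singular design matrix; refit with ridge > 0 (ReComBat) "
                "or drop collinear covariates"
            )
    coefs = np.linalg.solve(gram, dmat.T @ y)            # (n_batches + p, d)
    batch_means = coefs[: len(batches)]                  # per-batch location
    beta = coefs[len(batches):] if p_cov else None

    weights = np.array([sizes[b] for b in batches], float) / n
    grand_mean = weights @ batch_means                   # a_f
    fitted = dmat @ coefs
    pooled_var = np.mean((y - fitted) ** 2, axis=0)      # sigma_f^2
    pooled_sd = np.sqrt(np.maximum(pooled_var, 1e-16))

    stand = y - grand_mean
    if beta is not None:
        stand = stand - np.asarray(design, float) @ beta
    z = stand / pooled_sd

    gamma_hat = np.empty((len(batches), d))
    delta2_hat = np.empty((len(batches), d))
    for i, b in enumerate(batches):
        zi = z[labels == b]
        gamma_hat[i] = zi.mean(axis=0)
        # ddof=0 keeps the per-batch scale consistent with the pooled sd, so a
        # single-batch fit is an exact identity and refits find delta* = 1
        delta2_hat[i] = zi.var(axis=0, ddof=0)
    delta2_hat = np.maximum(delta2_hat, 1e-12)

    eb_hyper: dict = {}
    if mode == "ls-only":
        gamma_star, delta2_star = gamma_hat, delta2_hat
    else:
        gamma_star = np.empty_like(gamma_hat)
        delta2_star = np.empty_like(delta2_hat)
        for i, b in enumerate(batches):
            g, d2, hyper = _eb_shrink(
                z[labels == b], gamma_hat[i], delta2_hat[i], sizes[b]
            )
            gamma_star[i], delta2_star[i] = g, d2
            eb_hyper[b] = hyper

    return CombatModel(
        batch_factor=batch_factor,
        batches=batches,
        batch_sizes=sizes,
        grand_mean=grand_mean,
        pooled_sd=pooled_sd,
        gamma_star=gamma_star,
        delta_star=np.sqrt(delta2_star),
        mode=mode,
        ridge=ridge,
        eb_hyper=eb_hyper,
        beta=beta,
    )


def _eb_shrink(
    z_batch: np.ndarray, gamma_hat: np.ndarray, delta2_hat: np.ndarray, n_i: int
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Parametric EB posterior means for one batch (standard iterative scheme).

    Cross-feature hyperpriors by method of moments: gamma_if ~ N(gbar, t2),
    delta2_if ~ InvGamma(a_prior, b_prior). Iterate the conditional posterior
    means until max change < EB_TOL.
    """
    gbar = gamma_hat.mean()
    t2 = gamma_hat.var(ddof=1)
    m = delta2_hat.mean()
    s2 = delta2_hat.var(ddof=1)
    if s2 <= 0:
        s2 = 1e-12
    a_prior = (2 * s2 + m**2) / s2
    b_prior = (m * s2 + m**3) / s2

    g_old = gamma_hat.copy()
    d2_old = delta2_hat.copy()
    # sum of squares around the current gamma estimate, per feature
    for _ in range(EB_MAX_ITER):
        g_new = (n_i * t2 * gamma_hat + d2_old * gbar) / (n_i * t2 + d2_old)
        sse = np.sum((z_batch - g_new) ** 2, axis=0)
        d2_new = (b_prior + 0.5 * sse) / (n_i / 2.0 + a_prior - 1.0)
        change = max(np.max(np.abs(g_new - g_old)), np.max(np.abs(d2_new - d2_old)))
        g_old, d2_old = g_new, d2_new
        if change < EB_TOL:
            break
    hyper = {"gamma_bar": gbar, "tau2": t2, "a_prior": a_prior, "b_prior": b_prior}
    return g_old, np.maximum(d2_old, 1e-12), hyper


# ---------------------------------------------------------------------------
# Applying
# ---------------------------------------------------------------------------

def combat_apply(
    model: CombatModel, table: LesionTable, design: np.ndarray | None = None
) -> LesionTable:
    """Correct a table with a fitted model: standardize, remove gamma*/delta*,
    restore the grand location (and covariate effects, if any).
    """
    labels = table.df[model.batch_factor].to_numpy()
    unseen = sorted(set(labels) - set(model.batches))
    if unseen:
        raise CombatApplyError(f"batch label(s) {unseen} not seen during fit")
    if (model.beta is None) != (design is None):
        raise CombatApplyError("design covariates must match the fitted model")

    y = table.features
    stand = y - model.grand_mean
    cov_part = 0.0
    if model.beta is not None:
        cov_part = np.asarray(design, float) @ model.beta
        stand = stand - cov_part
    z = stand / model.pooled_sd

    out = np.empty_like(z)
    for i, b in enumerate(model.batches):
        rows = labels == b
        if not rows.any():
            continue
        out[rows] = (z[rows] - model.gamma_star[i]) / model.delta_star[i]
    corrected = out * model.pooled_sd + model.grand_mean + cov_part
    return table.with_features(corrected)


# ---------------------------------------------------------------------------
# Cascades and order selection
# ---------------------------------------------------------------------------

@dataclass
class HarmonizationPlan:
    """Ordered multi-factor correction: one (factor, method, ridge) per step."""

    factors: list[str]
    method: str = "combat"            # "combat" | "recombat"
    ridge: float = 1e-3               # used by recombat steps

    def __post_init__(self) -> None:
        if not self.factors:
            raise ValueError("plan must list at least one factor")
        if len(set(self.factors)) != len(self.factors):
            raise ValueError("plan factors must be distinct")
        if self.method not in ("combat", "recombat"):
            raise ValueError(f"unknown method {self.method!r}")

    def step_ridge(self) -> float:
        return self.ridge if self.method == "recombat" else 0.0


def sequential_harmonize(
    table: LesionTable, plan: HarmonizationPlan, mode: str = "eb-parametric"
) -> tuple[LesionTable, list[CombatModel]]:
    """Fit-and-apply one L/S correction per factor, in plan order, each step
    consuming the previous step's output.
    """
    models = []
    current = table
    for step, factor in enumerate(plan.factors):
        try:
            model = combat_fit(current, factor, mode=mode, ridge=plan.step_ridge())
            current = combat_apply(model, current)
        except (CombatFitError, CombatApplyError) as exc:
            raise type(exc)(f"cascade step {step} ({factor}): {exc}") from exc
        models.append(model)
    return current, models


def _association_count(table: LesionTable, factors: list[str], alpha: float) -> dict[str, int]:
    """Per factor, count features still associated with the factor labels
    (Kruskal-Wallis p < alpha) after correction.
    """
    x = table.features
    counts = {}
    for factor in factors:
        labels = table.df[factor].to_numpy()
        groups_idx = [labels == b for b in sorted(set(labels))]
        c = 0
        for f in range(x.shape[1]):
            samples = [x[g, f] for g in groups_idx]
            if np.ptp(x[:, f]) == 0:
                continue  # constant feature: no association
            try:
                p = stats.kruskal(*samples).pvalue
            except ValueError:  # all values identical within the test
                continue
            if p < alpha:
                c += 1
        counts[factor] = c
    return counts


def opnested_select_order(
    table: LesionTable,
    factors: list[str],
    alpha: float = 0.05,
    method: str = "combat",
    ridge: float = 1e-3,
) -> tuple[tuple[str, ...], LesionTable, dict]:
    """Simplified optimal-order nested correction.

    Runs the sequential cascade for every permutation of the factors and keeps
    the order that leaves the fewest residual (feature, factor) associations
    (rank-based Kruskal-Wallis at level ``alpha``); ties go to the first
    permutation in lexicographic enumeration.
    """
    if len(factors) < 2:
        raise ValueError("order selection needs at least 2 factors")
    report: dict = {}
    best_order, best_table, best_count = None, None, None
    for perm in itertools.permutations(sorted(factors)):
        corrected, _ = sequential_harmonize(
            table, HarmonizationPlan(list(perm), method=method, ridge=ridge)
        )
        counts = _association_count(corrected, list(perm), alpha)
        total = sum(counts.values())
        report["-".join(perm)] = {"per_factor": counts, "total": total}
        if best_count is None or total < best_count:
            best_order, best_table, best_count = perm, corrected, total
    return best_order, best_table, report
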