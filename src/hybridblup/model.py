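"""Ridge-regression mixed model for hybrid prediction.

The model relates hybrid phenotypes to the predictor states of the two
parental lines:

    y = 1 b0 + F u + M v + e,
    u_j ~ N(0, s2_f),  v_j ~ N(0, s2_m),  e_i ~ N(0, s2_e)

with a fixed intercept b0 and every predictor effect treated as a random
(ridge-shrunken) effect, a separate variance for the female- and
male-parent block.  Variance components are estimated by REML; effects
solve Henderson's mixed model equations.  Specific combining ability is
deliberately absent from the model and acts as part of the residual.

Two algebraically equivalent solvers are provided: the explicit
(1+2p)-dimensional mixed-model-equation system, and an n-dimensional
route through V = F F' s2_f + M M' s2_m + I s2_e (the Woodbury form used
when p >> n).  Prediction of new hybrids is y* = b0 + F* u + M* v, and
predicted general combining abilities are g_f* = F* u, g_m* = M* v.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

from .errors import ConfigError, DataError, FitError, NumericalError
from .predictors import DesignPair, build_design

__all__ = [
    "VarianceComponents",
    "FittedModel",
    "restricted_log_likelihood",
    "reml_fit",
    "solve_mme",
    "fit",
    "predict_hybrids",
    "predict_gca",
]

_LOG10_RATIO_BOUNDS = (-6.0, 6.0)
_GRID = np.arange(-4.0, 4.01, 2.0)
_ZERO_RATIO = 10.0 ** (_LOG10_RATIO_BOUNDS[0] + 0.25)  # boundary => component zeroed


@dataclass(frozen=True)
class VarianceComponents:
    """REML variance components of the two-block ridge model."""

    sigma2_f: float
    sigma2_m: float
    sigma2_e: float
    reml_loglik: float | None = None
    converged: bool = True

    def __post_init__(self):
        if min(self.sigma2_f, self.sigma2_m, self.sigma2_e) < 0:
            raise ConfigError("variance components must be >= 0")
        if self.sigma2_f + self.sigma2_m + self.sigma2_e == 0:
            raise ConfigError("at least one variance component must be > 0")


@dataclass(frozen=True)
class FittedModel:
    """Intercept, BLUP effect vectors and the design metadata needed to
    build F*/M* for new hybrids (predictor ids and normalization maxima)."""

    beta0: float
    u_hat: np.ndarray
    v_hat: np.ndarray
    vc: VarianceComponents
    predictor_ids: tuple[str, ...]
    col_max_f: np.ndarray
    col_max_m: np.ndarray


def _unpack(design) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(design, DesignPair):
        return design.F, design.M
    F, M = design
    return np.asarray(F, dtype=float), np.asarray(M, dtype=float)


def _kernels(F, M, K_f=None, K_m=None):
    if K_f is None:
        K_f = F @ F.T
    if K_m is None:
        K_m = M @ M.T
    return K_f, K_m


def _h_factor(K_f, K_m, gamma_f, gamma_m):
    n = K_f.shape[0]
    H = gamma_f * K_f + gamma_m * K_m
    H[np.diag_indices(n)] += 1.0
    try:
        return linalg.cho_factor(H, lower=True)
    except linalg.LinAlgError as exc:  # pragma: no cover - PD by construction
        raise NumericalError(f"covariance matrix not positive definite: {exc}") from exc


def _gls_pieces(cho, y):
    """Intercept GLS fit under H: returns (b0, r, quad, logdet_H, denom)."""
    n = y.shape[0]
    ones = np.ones(n)
    Hi_ones = linalg.cho_solve(cho, ones)
    Hi_y = linalg.cho_solve(cho, y)
    denom = ones @ Hi_ones
    b0 = (ones @ Hi_y) / denom
    r = y - b0
    quad = r @ linalg.cho_solve(cho, r)
    logdet = 2.0 * np.log(np.diag(cho[0])).sum()
    return b0, r, quad, logdet, denom


def restricted_log_likelihood(design, y, vc: VarianceComponents) -> float:
    """Restricted log-likelihood of ``y`` under the model's covariance.

    Defined as the Gaussian log-density of A'y where A is any orthonormal
    basis of the orthogonal complement of the intercept column; the value
    is invariant to the choice of basis.  The intercept is thereby
    profiled out.  Finite whenever V is positive definite.
    """
    F, M = _unpack(design)
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if F.shape[0] != n or M.shape[0] != n:
        raise DataError("design and response dimensions disagree")
    s2e = vc.sigma2_e
    if s2e <= 0:
        raise ConfigError("sigma2_e must be > 0 to evaluate the likelihood")
    K_f, K_m = _kernels(F, M)
    cho = _h_factor(K_f, K_m, vc.sigma2_f / s2e, vc.sigma2_m / s2e)
    _, _, quad, logdet_h, denom = _gls_pieces(cho, y)
    return -0.5 * (
        (n - 1) * math.log(2.0 * math.pi)
        + (n - 1) * math.log(s2e)
        + logdet_h
        + math.log(denom / n)
        + quad / s2e
    )


def _profiled_objective(K_f, K_m, y):
    """Return f(log10 gamma_f, log10 gamma_m) -> -profiled REML loglik."""
    n = y.shape[0]
    lo, hi = _LOG10_RATIO_BOUNDS

    def objective(t):
        tf = float(np.clip(t[0], lo, hi))
        tm = float(np.clip(t[1], lo, hi))
        cho = _h_factor(K_f, K_m, 10.0 ** tf, 10.0 ** tm)
        _, _, quad, logdet_h, denom = _gls_pieces(cho, y)
        s2e = quad / (n - 1)
        if s2e <= 0 or not np.isfinite(s2e):
            return np.inf
        ll = -0.5 * (
            (n - 1) * (math.log(2.0 * math.pi) + math.log(s2e) + 1.0)
            + logdet_h
            + math.log(denom / n)
        )
        return -ll

    return objective


def reml_fit(design, y, K_f=None, K_m=None) -> VarianceComponents:
    """Estimate (s2_f, s2_m, s2_e) by REML.

    The two variance ratios gamma_f = s2_f/s2_e and gamma_m = s2_m/s2_e
    are optimized on a log10 scale over [1e-6, 1e6] with a deterministic
    coarse grid followed by Nelder-Mead refinement (objective tolerance
    1e-8); the error variance is profiled out analytically.  A ratio that
    ends on the lower boundary is reported as an exactly zero component.

    ``K_f``/``K_m`` optionally supply precomputed F F' and M M' kernels
    (used by cross-validation to avoid rebuilding them per run).
    """
    F, M = _unpack(design)
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if n < 3:
        raise DataError("REML needs at least 3 observations")
    s2_total = float(np.var(y, ddof=1))
    if F.shape[1] == 0 and M.shape[1] == 0:
        return VarianceComponents(0.0, 0.0, s2_total, converged=True)
    K_f, K_m = _kernels(F, M, K_f, K_m)
    obj = _profiled_objective(K_f, K_m, y)

    best_t, best_val = None, np.inf
    for tf in _GRID:
        for tm in _GRID:
            val = obj((tf, tm))
            if val < best_val:
                best_t, best_val = (tf, tm), val
    res = optimize.minimize(
        obj,
        np.asarray(best_t, dtype=float),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 600},
    )
    if not res.success and res.fun > best_val + 1e-6:
        raise FitError(
            "REML optimizer failed to converge", best=(best_t, -best_val)
        )
    t_opt = np.clip(res.x if res.fun <= best_val else np.asarray(best_t), *_LOG10_RATIO_BOUNDS)
    gamma_f, gamma_m = 10.0 ** t_opt[0], 10.0 ** t_opt[1]
    if gamma_f <= _ZERO_RATIO:
        gamma_f = 0.0
    if gamma_m <= _ZERO_RATIO:
        gamma_m = 0.0
    cho = _h_factor(K_f, K_m, gamma_f, gamma_m)
    _, _, quad, _, _ = _gls_pieces(cho, y)
    s2e = float(quad / (n - 1))
    vc = VarianceComponents(
        sigma2_f=float(gamma_f * s2e),
        sigma2_m=float(gamma_m * s2e),
        sigma2_e=s2e,
        reml_loglik=float(-min(res.fun, best_val)),
        converged=bool(res.success),
    )
    return vc


def solve_mme(design, y, vc: VarianceComponents, method: str = "auto",
              K_f=None, K_m=None) -> FittedModel:
    """Solve Henderson's mixed model equations for (b0, u, v).

    ``method``:
      * ``"mme"``  — assemble and solve the explicit (1+2p) system with
        ridge penalties lambda_f = s2_e/s2_f and lambda_m = s2_e/s2_m;
      * ``"gls"``  — the equivalent n-dimensional route
        u = s2_f F' V^{-1} (y - 1 b0) (Woodbury form, used for p >> n);
      * ``"auto"`` — "mme" when 1 + 2p <= n, else "gls".

    A zero variance component drops its block (effects fixed at zero)
    instead of inverting a near-singular system.
    """
    F, M = _unpack(design)
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if F.shape[0] != n or M.shape[0] != n:
        raise DataError("design and response dimensions disagree")
    if vc.sigma2_e <= 0:
        raise ConfigError("sigma2_e must be > 0 to solve the MME")
    p_f, p_m = F.shape[1], M.shape[1]
    use_f = vc.sigma2_f > 0 and p_f > 0
    use_m = vc.sigma2_m > 0 and p_m > 0

    if method == "auto":
        method = "mme" if 1 + p_f * use_f + p_m * use_m <= n else "gls"
    if method not in ("mme", "gls"):
        raise ConfigError(f"unknown solver method {method!r}")

    u_hat = np.zeros(p_f)
    v_hat = np.zeros(p_m)

    if not use_f and not use_m:
        beta0 = float(y.mean())
    elif method == "mme":
        blocks_x = [np.ones((n, 1))]
        penalties = [0.0]
        if use_f:
            blocks_x.append(F)
            penalties.extend([vc.sigma2_e / vc.sigma2_f] * p_f)
        if use_m:
            blocks_x.append(M)
            penalties.extend([vc.sigma2_e / vc.sigma2_m] * p_m)
        W = np.hstack(blocks_x)
        C = W.T @ W
        C[np.diag_indices_from(C)] += np.asarray(penalties)
        rhs = W.T @ y
        try:
            sol = linalg.solve(C, rhs, assume_a="pos")
        except linalg.LinAlgError as exc:
            raise NumericalError(f"singular MME coefficient matrix: {exc}") from exc
        beta0 = float(sol[0])
        k = 1
        if use_f:
            u_hat = sol[k:k + p_f]
            k += p_f
        if use_m:
            v_hat = sol[k:k + p_m]
    else:
        gamma_f = vc.sigma2_f / vc.sigma2_e if use_f else 0.0
        gamma_m = vc.sigma2_m / vc.sigma2_e if use_m else 0.0
        Kf, Km = _kernels(F if use_f else np.zeros((n, 0)),
                          M if use_m else np.zeros((n, 0)),
                          K_f if use_f else None, K_m if use_m else None)
        cho = _h_factor(Kf, Km, gamma_f, gamma_m)
        b0, r, _, _, _ = _gls_pieces(cho, y)
        Hi_r = linalg.cho_solve(cho, r)
        beta0 = float(b0)
        if use_f:
            u_hat = gamma_f * (F.T @ Hi_r)
        if use_m:
            v_hat = gamma_m * (M.T @ Hi_r)

    ids = design.predictor_ids if isinstance(design, DesignPair) else tuple(
        f"p{j}" for j in range(p_f)
    )
    cmf = design.col_max_f if isinstance(design, DesignPair) else np.ones(p_f)
    cmm = design.col_max_m if isinstance(design, DesignPair) else np.ones(p_m)
    return FittedModel(
        beta0=beta0,
        u_hat=np.asarray(u_hat, dtype=float),
        v_hat=np.asarray(v_hat, dtype=float),
        vc=vc,
        predictor_ids=ids,
        col_max_f=np.asarray(cmf, dtype=float),
        col_max_m=np.asarray(cmm, dtype=float),
    )


def fit(design, y, method: str = "auto", K_f=None, K_m=None) -> FittedModel:
    """REML variance estimation followed by the MME solve, in one call."""
    vc = reml_fit(design, y, K_f=K_f, K_m=K_m)
    return solve_mme(design, y, vc, method=method, K_f=K_f, K_m=K_m)


def predict_from_design(model: FittedModel, design: DesignPair) -> np.ndarray:
    """y* = b0 + F* u + M* v for a pre-built design pair."""
    if design.p != model.u_hat.shape[0]:
        raise DataError("design column count does not match the fitted model")
    return model.beta0 + design.F @ model.u_hat + design.M @ model.v_hat


def predict_hybrids(model: FittedModel, new_pairs, pools, markers=None,
                    expression=None, genes=None) -> np.ndarray:
    """Predict genotypic values of (possibly unseen) hybrids.

    F*/M* are built from the parents' predictor data with the
    normalization maxima stored in the fitted model, then
    y* = b0 + F* u + M* v.  Rows align with ``new_pairs``.
    """
    design = build_design(
        new_pairs, pools, markers=markers, expression=expression, genes=genes,
        norm_maxima=(model.col_max_f, model.col_max_m),
    )
    if design.predictor_ids != model.predictor_ids:
        raise DataError("predictor ids do not match the fitted model")
    return predict_from_design(model, design)


def predict_gca(model: FittedModel, lines, pools, pool: str, markers=None,
                expression=None, genes=None) -> np.ndarray:
    """Predicted general combining abilities g_f* = F* u or g_m* = M* v.

    ``pool`` selects which effect vector applies ("female" or "male");
    every line must belong to that pool.
    """
    if pool not in ("female", "male"):
        raise ConfigError("pool must be 'female' or 'male'")
    lines = list(lines)
    valid = set(pools.female_lines if pool == "female" else pools.male_lines)
    bad = [ln for ln in lines if ln not in valid]
    if bad:
        raise ConfigError(f"line(s) not in the {pool} pool: {bad}")
    # build a design by pairing each line with an arbitrary mate from the
    # other pool; only the requested block is read
    if pool == "female":
        mate = pools.male_lines[0]
        pairs = [(ln, mate) for ln in lines]
    else:
        mate = pools.female_lines[0]
        pairs = [(mate, ln) for ln in lines]
    design = build_design(
        pairs, pools, markers=markers, expression=expression, genes=genes,
        norm_maxima=(model.col_max_f, model.col_max_m),
    )
    if design.predictor_ids != model.predictor_ids:
        raise DataError("predictor ids do not match the fitted model")
    if pool == "female":
        return design.F @ model.u_hat
    return design.M @ model.v_hat
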