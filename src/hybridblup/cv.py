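"""Type-2 and type-0 cross-validation of hybrid prediction accuracy.

A *type 2* hybrid is untested but both of its parents have testcross data
in the estimation set; a *type 0* hybrid has parents with no testcross
data at all.  On a complete female x male factorial:

* type 2 — sample a few lines from each pool (defaults 3 female, 5
  male); the crosses **among** the sampled lines form the validation set
  and every other cross the estimation set, so each validation parent
  still appears in estimation crosses with other mates;
* type 0 — sample estimation lines (defaults 5 female, 10 male); the
  estimation set is all crosses among them and the validation set all
  crosses among the remaining lines; mixed crosses are used in neither.

Each run refits the whole pipeline (design, REML, BLUP) on the estimation
crosses and scores the held-out crosses by the Pearson correlation
r(y, yhat) and the mean absolute prediction error.  Distributions over
many runs (default 1000) summarize accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .model import reml_fit, solve_mme
from .predictors import build_design, filter_markers, impute_missing, sample_transcripts
from .simulate import PoolAssignment, SyntheticDataset, mid_parent_heterosis

__all__ = [
    "CVScheme",
    "CVSummary",
    "make_type2_split",
    "make_type0_split",
    "run_cv",
    "pearson_r",
    "mean_abs_error",
    "PREDICTOR_SETS",
]

PREDICTOR_SETS = ("AFLP", "mRNA10k", "mRNAr1k", "combined")
_GENE_STREAM_TAG = 910  # distinguishes the per-run gene-sampling stream


@dataclass(frozen=True)
class CVScheme:
    """Cross-validation scheme parameters.

    ``n_female_selected``/``n_male_selected`` are the per-pool numbers of
    sampled lines (validation lines for type 2, estimation lines for
    type 0); defaults follow the study: (3, 5) and (5, 10).
    ``type2_literal_text`` swaps the type-2 estimation and validation
    sets, reproducing a literal reading under which the sampled block is
    the estimation set (the sets then violate the type-2 condition).
    """

    kind: str = "type2"
    n_female_selected: int | None = None
    n_male_selected: int | None = None
    n_runs: int = 1000
    base_seed: int = 0
    type2_literal_text: bool = False

    def __post_init__(self):
        if self.kind not in ("type2", "type0"):
            raise ConfigError(f"scheme kind must be 'type2' or 'type0', got {self.kind!r}")
        defaults = {"type2": (3, 5), "type0": (5, 10)}[self.kind]
        if self.n_female_selected is None:
            object.__setattr__(self, "n_female_selected", defaults[0])
        if self.n_male_selected is None:
            object.__setattr__(self, "n_male_selected", defaults[1])
        if self.n_runs < 1:
            raise ConfigError("n_runs must be >= 1")

    def validate_pools(self, pools: PoolAssignment):
        nf, nm = len(pools.female_lines), len(pools.male_lines)
        if not (0 < self.n_female_selected < nf and 0 < self.n_male_selected < nm):
            raise ConfigError(
                f"selected counts ({self.n_female_selected}, {self.n_male_selected}) "
                f"must be strictly between 0 and the pool sizes ({nf}, {nm})"
            )


@dataclass
class CVSummary:
    """Per-run accuracies and their summaries over all runs."""

    runs: pd.DataFrame  # columns: run, r, mae, n_validation
    n_degenerate: int
    scheme: CVScheme
    predictor_set: str
    response: str

    @property
    def median_r(self) -> float:
        return float(self.runs["r"].median())

    @property
    def mean_r(self) -> float:
        return float(self.runs["r"].mean())

    @property
    def median_mae(self) -> float:
        return float(self.runs["mae"].median())

    @property
    def mean_mae(self) -> float:
        return float(self.runs["mae"].mean())


def _sample_lines(pools: PoolAssignment, scheme: CVScheme, run_index: int):
    rng = np.random.default_rng(scheme.base_seed + run_index)
    sel_f = sorted(rng.choice(len(pools.female_lines), scheme.n_female_selected, replace=False))
    sel_m = sorted(rng.choice(len(pools.male_lines), scheme.n_male_selected, replace=False))
    return (
        [pools.female_lines[i] for i in sel_f],
        [pools.male_lines[i] for i in sel_m],
    )


def make_type2_split(pools: PoolAssignment, scheme: CVScheme, run_index: int):
    """Split the full factorial for one type-2 run.

    Returns (estimation_pairs, validation_pairs).  The crosses among the
    sampled lines are held out, so both parents of every validation
    hybrid occur in estimation crosses.
    """
    scheme.validate_pools(pools)
    sel_f, sel_m = _sample_lines(pools, scheme, run_index)
    in_f, in_m = set(sel_f), set(sel_m)
    block = [(f, m) for f, m in product(pools.female_lines, pools.male_lines)
             if f in in_f and m in in_m]
    rest = [(f, m) for f, m in product(pools.female_lines, pools.male_lines)
            if not (f in in_f and m in in_m)]
    if scheme.type2_literal_text:
        return block, rest
    return rest, block


def make_type0_split(pools: PoolAssignment, scheme: CVScheme, run_index: int):
    """Split the full factorial for one type-0 run.

    Estimation = all crosses among the sampled lines; validation = all
    crosses among the unselected lines; crosses between a selected and an
    unselected line are used in neither set.
    """
    scheme.validate_pools(pools)
    nf, nm = len(pools.female_lines), len(pools.male_lines)
    if scheme.n_female_selected >= nf or scheme.n_male_selected >= nm:
        raise ConfigError("type-0 needs >= 1 unselected line per pool")
    sel_f, sel_m = _sample_lines(pools, scheme, run_index)
    out_f = [ln for ln in pools.female_lines if ln not in set(sel_f)]
    out_m = [ln for ln in pools.male_lines if ln not in set(sel_m)]
    estimation = list(product(sel_f, sel_m))
    validation = list(product(out_f, out_m))
    return estimation, validation


def make_split(pools: PoolAssignment, scheme: CVScheme, run_index: int):
    if scheme.kind == "type2":
        return make_type2_split(pools, scheme, run_index)
    return make_type0_split(pools, scheme, run_index)


def pearson_r(y, yhat) -> float:
    """Pearson correlation; NaN (with a warning) if either input is constant."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise DataError("pearson_r needs two equal-length vectors of size >= 2")
    if not np.all(np.isfinite(yhat)) or not np.all(np.isfinite(y)):
        raise DataError("pearson_r inputs must be finite")
    if np.std(y) == 0 or np.std(yhat) == 0:
        warnings.warn("correlation undefined: constant input vector", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(y, yhat)[0, 1])


def mean_abs_error(y, yhat) -> float:
    """Average absolute prediction error sum|yhat_i - y_i| / n."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size == 0:
        raise DataError("mean_abs_error needs two equal-length non-empty vectors")
    return float(np.mean(np.abs(yhat - y)))


def _gene_rng(scheme: CVScheme, run_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([scheme.base_seed, run_index, _GENE_STREAM_TAG])
    )


def run_cv(
    dataset: SyntheticDataset,
    predictor_set: str,
    scheme: CVScheme,
    response: str = "performance",
    genes: list[str] | None = None,
    n_runs: int | None = None,
    mrnar1k_size: int = 1000,
) -> CVSummary:
    """Run the full cross-validation loop on a factorial dataset.

    ``predictor_set`` is one of ``AFLP`` (filtered + imputed markers),
    ``mRNA10k`` (the transcript panel, or ``genes`` if given),
    ``mRNAr1k`` (a fresh random subsample of ``mrnar1k_size`` transcripts
    per run) or ``combined`` (markers and the mRNAr1k subsample).  Each
    run: split -> build estimation design -> REML -> MME -> predict the
    validation crosses -> record r(y, yhat) and the mean absolute error.
    Runs with an undefined correlation are recorded as missing, counted,
    and excluded from medians/means.
    """
    if predictor_set not in PREDICTOR_SETS:
        raise ConfigError(f"predictor_set must be one of {PREDICTOR_SETS}")
    if response not in ("performance", "MPH"):
        raise ConfigError("response must be 'performance' or 'MPH'")
    scheme.validate_pools(dataset.pools)
    n_runs = scheme.n_runs if n_runs is None else n_runs
    pools = dataset.pools

    hybrids = dataset.hybrids
    if response == "MPH":
        hybrids = mid_parent_heterosis(hybrids, dataset.per_se)
        y_all = hybrids.set_index(["female", "male"])["mph"]
    else:
        y_all = hybrids.set_index(["female", "male"])["value"]
    expected = set(product(pools.female_lines, pools.male_lines))
    if set(y_all.index) != expected:
        raise DataError("dataset must contain phenotypes for every factorial cross")

    markers = None
    if predictor_set in ("AFLP", "combined"):
        markers = impute_missing(filter_markers(dataset.markers).matrix, pools)
    expression = dataset.expression
    gene_pool = list(genes) if genes is not None else list(expression.columns)

    # full-factorial design built once; runs subset its rows (expression
    # normalization maxima are the global per-pool maxima by default)
    all_pairs = [(f, m) for f, m in product(pools.female_lines, pools.male_lines)]
    pair_index = {pair: i for i, pair in enumerate(all_pairs)}
    resample_genes = predictor_set in ("mRNAr1k", "combined")
    base_design = build_design(
        all_pairs, pools,
        markers=markers,
        expression=None if predictor_set == "AFLP" else expression,
        genes=None if predictor_set == "AFLP" else gene_pool,
    )
    K_f_full = K_m_full = None
    if not resample_genes:
        K_f_full = base_design.F @ base_design.F.T
        K_m_full = base_design.M @ base_design.M.T
    col_of = {pid: i for i, pid in enumerate(base_design.predictor_ids)}
    y_vec = y_all.loc[list(all_pairs)].to_numpy(dtype=float)

    rows = []
    n_degenerate = 0
    for run in range(n_runs):
        est_pairs, val_pairs = make_split(pools, scheme, run)
        est_idx = np.array([pair_index[p] for p in est_pairs])
        val_idx = np.array([pair_index[p] for p in val_pairs])

        if resample_genes:
            sub_genes = sample_transcripts(gene_pool, mrnar1k_size, _gene_rng(scheme, run))
            cols = np.array([col_of[g] for g in sub_genes])
            if predictor_set == "combined":
                n_mk = markers.shape[1]
                cols = np.concatenate([np.arange(n_mk), cols])
            F_all = base_design.F[:, cols]
            M_all = base_design.M[:, cols]
            F_est, M_est = F_all[est_idx], M_all[est_idx]
            F_val, M_val = F_all[val_idx], M_all[val_idx]
            K_f = F_est @ F_est.T
            K_m = M_est @ M_est.T
        else:
            F_est, M_est = base_design.F[est_idx], base_design.M[est_idx]
            F_val, M_val = base_design.F[val_idx], base_design.M[val_idx]
            K_f = K_f_full[np.ix_(est_idx, est_idx)]
            K_m = K_m_full[np.ix_(est_idx, est_idx)]

        y_est = y_vec[est_idx]
        y_val = y_vec[val_idx]
        vc = reml_fit((F_est, M_est), y_est, K_f=K_f, K_m=K_m)
        fitted = solve_mme((F_est, M_est), y_est, vc, method="gls", K_f=K_f, K_m=K_m)
        y_pred = fitted.beta0 + F_val @ fitted.u_hat + M_val @ fitted.v_hat

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = pearson_r(y_val, y_pred)
        if np.isnan(r):
            n_degenerate += 1
        rows.append((run, r, mean_abs_error(y_val, y_pred), len(val_pairs)))

    runs_df = pd.DataFrame(rows, columns=["run", "r", "mae", "n_validation"])
    return CVSummary(
        runs=runs_df,
        n_degenerate=n_degenerate,
        scheme=scheme,
        predictor_set=predictor_set,
        response=response,
    )
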