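"""Predictor preparation: marker filters, imputation, the transcript
differential-expression screen, and assembly of the F / M design matrices.

Marker matrices are pandas DataFrames (rows = parental lines, columns =
marker ids) with entries in {0, 1, NaN}; expression matrices hold strictly
positive linear-scale intensities.  The design pair (F, M) codes, for each
hybrid, the predictor states of its female and male parent.  Expression
columns are normalized by the per-pool column maximum

    f_ij = o_ij / max_k o_kj      (k over the pool's parental lines)

so every expression column of F and M has maximum 1; marker columns are
0/1 and need no normalization (their column maximum is already 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DataError
from .simulate import PoolAssignment

__all__ = [
    "DesignPair",
    "MarkerFilterResult",
    "gene_diversity",
    "one_way_anova_pvalues",
    "filter_markers",
    "impute_missing",
    "filter_transcripts",
    "sample_transcripts",
    "build_design",
]


def gene_diversity(column) -> float:
    """Expected heterozygosity 2p(1-p) of a dominant marker column.

    ``p`` is the band frequency among non-missing entries.  Lies in
    [0, 0.5]; 0 for monomorphic columns, 0.5 at p = 1/2.
    """
    values = pd.Series(column).dropna().to_numpy(dtype=float)
    if values.size == 0:
        raise DataError("gene diversity undefined for an all-missing column")
    p = values.mean()
    return float(2.0 * p * (1.0 - p))


@dataclass(frozen=True)
class MarkerFilterResult:
    matrix: pd.DataFrame
    n_removed_missing: int
    n_removed_diversity: int
    n_removed_total: int


def filter_markers(
    markers: pd.DataFrame, max_missing: float = 0.10, min_diversity: float = 0.2
) -> MarkerFilterResult:
    """Drop marker columns with too many missing values or low diversity.

    A column is retained iff its missing fraction is <= ``max_missing``
    AND its gene diversity is >= ``min_diversity``.  Column order is
    preserved.  Removal counts are reported per criterion (a column can
    fail both).
    """
    values = markers.to_numpy(dtype=float)
    n_lines = values.shape[0]
    missing_frac = np.isnan(values).mean(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(values, axis=0)
    diversity = 2.0 * p * (1.0 - p)
    all_missing = missing_frac == 1.0

    fail_missing = missing_frac > max_missing
    fail_diversity = all_missing | (diversity < min_diversity)
    keep = ~(fail_missing | fail_diversity)
    if not keep.any():
        import warnings

        warnings.warn("marker filter removed every column", stacklevel=2)
    return MarkerFilterResult(
        matrix=markers.loc[:, markers.columns[keep]],
        n_removed_missing=int(fail_missing.sum()),
        n_removed_diversity=int(fail_diversity.sum()),
        n_removed_total=int((~keep).sum()),
    )


def impute_missing(markers: pd.DataFrame, pools: PoolAssignment) -> pd.DataFrame:
    """Replace missing marker entries by the within-pool band frequency.

    Mean imputation within the line's heterotic pool; leaves observed
    entries (and hence observed column means) untouched.  Raises if a
    column is entirely missing within a pool that contains missing
    entries for it.
    """
    out = markers.copy()
    for pool_lines in (pools.female_lines, pools.male_lines):
        lines = [ln for ln in pool_lines if ln in markers.index]
        if not lines:
            continue
        block = out.loc[lines]
        has_missing = block.isna().any(axis=0)
        if has_missing.any():
            freqs = block.mean(axis=0)  # skips NaN
            dead = has_missing & freqs.isna()
            if dead.any():
                raise DataError(
                    f"marker(s) entirely missing within a pool: {list(block.columns[dead])[:5]}"
                )
            out.loc[lines] = block.fillna(freqs)
    return out


def one_way_anova_pvalues(values: np.ndarray, codes: np.ndarray):
    """Per-column one-way F-test p-values across groups, vectorized.

    ``values`` is observations x columns, ``codes`` the integer group of
    each row.  Columns with zero within-group variance get p = 0 when the
    group means differ and p = 1 when they do not.  Returns (pvals,
    group_means).
    """
    counts = np.bincount(codes)
    k = counts.size
    n = values.shape[0]
    group_sums = np.zeros((k, values.shape[1]))
    np.add.at(group_sums, codes, values)
    group_means = group_sums / counts[:, None]
    grand_mean = values.mean(axis=0)
    ss_between = (counts[:, None] * (group_means - grand_mean) ** 2).sum(axis=0)
    ss_within = ((values - group_means[codes]) ** 2).sum(axis=0)
    df_between, df_within = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = (ss_between / df_between) / (ss_within / df_within)
    pvals = stats.f.sf(f_stat, df_between, df_within)
    degenerate = ss_within == 0
    pvals[degenerate] = np.where(ss_between[degenerate] > 0, 0.0, 1.0)
    return pvals, group_means


def filter_transcripts(
    expression_replicates: pd.DataFrame,
    fdr: float = 0.01,
    min_fold: float = 1.3,
    min_log2_intensity: float = 8.0,
) -> list[str]:
    """Differential-expression screen over parental lines.

    Retains genes that (a) vary significantly across lines by a per-gene
    one-way F-test with Benjamini-Hochberg control at ``fdr``, (b) show a
    maximal pairwise line-mean difference of at least log2(``min_fold``)
    on the log2 scale, and (c) have mean log2 intensity of at least
    ``min_log2_intensity``.  Deterministic given its input.

    ``expression_replicates`` must carry a (line, replicate) MultiIndex
    with equal replicate counts per line (>= 2) and >= 2 lines.
    """
    if not isinstance(expression_replicates.index, pd.MultiIndex):
        raise ConfigError(
            "replicate structure absent: expression needs a (line, replicate) "
            "MultiIndex; skip the differential-expression screen otherwise"
        )
    if (expression_replicates.to_numpy() <= 0).any():
        raise DataError("expression intensities must be strictly positive")
    log2 = np.log2(expression_replicates.to_numpy(dtype=float))
    lines = expression_replicates.index.get_level_values(0)
    codes, uniques = pd.factorize(lines, sort=False)
    k = len(uniques)
    counts = np.bincount(codes)
    if k < 2:
        raise ConfigError("the screen needs >= 2 lines")
    if counts.min() < 2:
        raise ConfigError("the screen needs >= 2 replicates per line")
    if counts.min() != counts.max():
        raise DataError("replicate counts must be equal across lines")

    pvals, group_means = one_way_anova_pvalues(log2, codes)
    significant = multipletests(pvals, alpha=fdr, method="fdr_bh")[0]
    fold_ok = (group_means.max(axis=0) - group_means.min(axis=0)) >= np.log2(min_fold)
    intensity_ok = log2.mean(axis=0) >= min_log2_intensity
    keep = significant & fold_ok & intensity_ok
    return [g for g, k_ in zip(expression_replicates.columns, keep) if k_]


def sample_transcripts(genes: list[str], k: int = 1000, rng=None) -> list[str]:
    """Uniform sample of ``k`` gene ids without replacement.

    The result is sorted back into the original order of ``genes`` so the
    chosen set (not the draw order) determines downstream behaviour.
    """
    if k > len(genes):
        raise ConfigError(f"cannot sample {k} genes from {len(genes)} available")
    rng = np.random.default_rng(rng)
    idx = rng.choice(len(genes), size=k, replace=False)
    idx.sort()
    return [genes[i] for i in idx]


@dataclass(frozen=True)
class DesignPair:
    """F and M design matrices for a list of hybrids, plus the per-pool
    column maxima used for normalization (reused verbatim when building
    designs for new, unseen lines)."""

    hybrids: tuple[tuple[str, str], ...]
    F: np.ndarray
    M: np.ndarray
    predictor_ids: tuple[str, ...]
    col_max_f: np.ndarray
    col_max_m: np.ndarray
    n_female_lines: int
    n_male_lines: int

    @property
    def n(self) -> int:
        return self.F.shape[0]

    @property
    def p(self) -> int:
        return self.F.shape[1]

    @property
    def norm_maxima(self) -> tuple[np.ndarray, np.ndarray]:
        return self.col_max_f, self.col_max_m


def _pool_matrix(
    table: pd.DataFrame, lines: list[str], what: str
) -> pd.DataFrame:
    missing = [ln for ln in lines if ln not in table.index]
    if missing:
        raise DataError(f"no {what} data for line(s): {missing}")
    return table.loc[lines]


def build_design(
    hybrids,
    pools: PoolAssignment,
    markers: pd.DataFrame | None = None,
    expression: pd.DataFrame | None = None,
    genes: list[str] | None = None,
    norm_maxima: tuple[np.ndarray, np.ndarray] | None = None,
    norm_lines: tuple[list[str], list[str]] | None = None,
) -> DesignPair:
    """Assemble the (F, M) design pair for ``hybrids``.

    ``hybrids`` is a sequence of (female, male) id pairs (or a DataFrame
    with ``female``/``male`` columns).  Marker entries enter F/M as their
    0/1 (or imputed fractional) states; expression entries are divided by
    the per-pool column maximum.  When both sources are given the design
    is the column-wise concatenation [markers | expression].

    ``norm_maxima`` reuses previously computed maxima (for predicting new
    lines with a fitted model); ``norm_lines`` restricts the lines over
    which maxima are taken (e.g. an estimation set only).  By default
    maxima are taken over all lines of each pool present in the table.
    """
    if markers is None and expression is None:
        raise ConfigError("need at least one of markers / expression")
    if isinstance(hybrids, pd.DataFrame):
        pairs = list(zip(hybrids["female"], hybrids["male"]))
    else:
        pairs = [(f, m) for f, m in hybrids]
    fem = [f for f, _ in pairs]
    mal = [m for _, m in pairs]
    unknown = (set(fem) - set(pools.female_lines)) | (set(mal) - set(pools.male_lines))
    if unknown:
        raise DataError(f"parent id(s) not in the pool assignment: {sorted(unknown)}")

    blocks_f, blocks_m, ids = [], [], []
    max_f_parts, max_m_parts = [], []

    if markers is not None:
        if markers.isna().any().any():
            raise DataError("marker matrix contains missing values; impute first")
        mk_f = _pool_matrix(markers, list(dict.fromkeys(fem)), "marker")
        mk_m = _pool_matrix(markers, list(dict.fromkeys(mal)), "marker")
        blocks_f.append(mk_f.loc[fem].to_numpy(dtype=float))
        blocks_m.append(mk_m.loc[mal].to_numpy(dtype=float))
        ids.extend(markers.columns)
        ones = np.ones(markers.shape[1])
        max_f_parts.append(ones)
        max_m_parts.append(ones.copy())

    if expression is not None:
        expr = expression if genes is None else expression.loc[:, list(genes)]
        if (expr.to_numpy() <= 0).any():
            raise DataError("expression intensities must be strictly positive")
        if norm_maxima is not None:
            off = blocks_f[0].shape[1] if blocks_f else 0
            mx_f = np.asarray(norm_maxima[0], dtype=float)[off:]
            mx_m = np.asarray(norm_maxima[1], dtype=float)[off:]
        else:
            if norm_lines is not None:
                lines_f, lines_m = norm_lines
            else:
                lines_f = [ln for ln in pools.female_lines if ln in expr.index]
                lines_m = [ln for ln in pools.male_lines if ln in expr.index]
            mx_f = _pool_matrix(expr, list(lines_f), "expression").to_numpy().max(axis=0)
            mx_m = _pool_matrix(expr, list(lines_m), "expression").to_numpy().max(axis=0)
        if (mx_f <= 0).any() or (mx_m <= 0).any():
            raise DataError("zero or negative normalization column maximum")
        ex_f = _pool_matrix(expr, list(dict.fromkeys(fem)), "expression")
        ex_m = _pool_matrix(expr, list(dict.fromkeys(mal)), "expression")
        blocks_f.append(ex_f.loc[fem].to_numpy(dtype=float) / mx_f)
        blocks_m.append(ex_m.loc[mal].to_numpy(dtype=float) / mx_m)
        ids.extend(expr.columns)
        max_f_parts.append(mx_f)
        max_m_parts.append(mx_m)

    return DesignPair(
        hybrids=tuple(pairs),
        F=np.hstack(blocks_f),
        M=np.hstack(blocks_m),
        predictor_ids=tuple(ids),
        col_max_f=np.concatenate(max_f_parts),
        col_max_m=np.concatenate(max_m_parts),
        n_female_lines=len(pools.female_lines),
        n_male_lines=len(pools.male_lines),
    )
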