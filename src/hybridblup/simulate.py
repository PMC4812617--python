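"""Synthetic two-pool factorial generator.

Emulates the data structure of a maize factorial mating design between two
divergent heterotic pools: a female ("flint") pool crossed to a male
("dent") pool, every cross realized, with dominant presence/absence DNA
markers and transcript-abundance profiles observed on the parental inbreds.

Hybrid phenotypes follow the classical combining-ability decomposition

    y_fm = mu + g_f + g_m + s_fm + e_fm

where ``g_f`` and ``g_m`` are general combining abilities (GCA) of the
female and male parent, ``s_fm`` the cross-specific specific combining
ability (SCA) and ``e_fm`` residual error.  GCAs are built from the causal
marker states of each line so that marker and transcript predictors carry a
recoverable genetic signal; SCA is drawn as an independent cross effect
because the prediction model deliberately omits it (it acts as structured
noise).  Transcript line means are linearly linked to causal marker states,
so expression predictors tag the same signal as the markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "GroundTruth",
    "PoolAssignment",
    "simulate_factorial",
    "mid_parent_heterosis",
]


@dataclass(frozen=True)
class PoolAssignment:
    """Line identifiers split into the female and male heterotic pool."""

    female_lines: tuple[str, ...]
    male_lines: tuple[str, ...]

    def __post_init__(self):
        overlap = set(self.female_lines) & set(self.male_lines)
        if overlap:
            raise DataError(f"lines assigned to both pools: {sorted(overlap)}")
        for pool in (self.female_lines, self.male_lines):
            if len(set(pool)) != len(pool):
                raise DataError("duplicate line ids within a pool")

    @property
    def all_lines(self) -> tuple[str, ...]:
        return self.female_lines + self.male_lines

    def pool_of(self, line: str) -> str:
        if line in self.female_lines:
            return "female"
        if line in self.male_lines:
            return "male"
        raise DataError(f"unknown line id: {line!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic factorial.

    Defaults mirror the study conditions: a 7 x 14 factorial (98 hybrids),
    970 dominant markers, 10,810 transcript predictors, and variance
    components giving broad-sense heritability 0.80 with an SCA:GCA
    variance ratio of 1.12 on a grain-yield-like scale (Mg/ha).
    """

    n_female_lines: int = 7
    n_male_lines: int = 14
    n_markers: int = 970
    n_transcripts: int = 10810
    n_causal: int = 50
    var_gca_f: float = 0.5
    var_gca_m: float = 0.5
    var_sca: float = 1.12
    var_error: float = 0.53
    missing_marker_rate: float = 0.02
    replicates_per_line: int = 3
    seed: int = 0
    # generator-shape parameters (not part of the variance decomposition)
    mean_phenotype: float = 11.7
    per_se_depression: float = 2.5
    per_se_gca_coef: float = 1.0
    band_freq_range: tuple[float, float] = (0.1, 0.9)
    baseline_log2_mean: float = 9.5
    baseline_log2_sd: float = 1.0
    transcript_linkage_density: float = 0.05
    transcript_effect_sd: float = 0.6
    transcript_noise_sd: float = 0.25

    def __post_init__(self):
        counts = {
            "n_female_lines": self.n_female_lines,
            "n_male_lines": self.n_male_lines,
            "n_markers": self.n_markers,
            "n_transcripts": self.n_transcripts,
            "n_causal": self.n_causal,
            "replicates_per_line": self.replicates_per_line,
        }
        for name, value in counts.items():
            if not isinstance(value, (int, np.integer)) or value < 1:
                raise ConfigError(f"{name} must be an integer >= 1, got {value!r}")
        for name in ("var_gca_f", "var_gca_m", "var_sca", "var_error"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)!r}")
        if not 0.0 <= self.missing_marker_rate <= 1.0:
            raise ConfigError(
                f"missing_marker_rate must lie in [0, 1], got {self.missing_marker_rate!r}"
            )
        if self.n_causal > self.n_markers:
            raise ConfigError(
                f"n_causal ({self.n_causal}) must not exceed n_markers ({self.n_markers})"
            )
        lo, hi = self.band_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigError(f"band_freq_range must satisfy 0 < lo <= hi < 1, got {self.band_freq_range!r}")

    @property
    def heritability(self) -> float:
        """Broad-sense heritability implied by the variance components."""
        genetic = self.var_gca_f + self.var_gca_m + self.var_sca
        total = genetic + self.var_error
        if total == 0:
            return float("nan")
        return genetic / total

    def replace(self, **changes) -> "SimulationConfig":
        current = {f.name: getattr(self, f.name) for f in dc_fields(self)}
        current.update(changes)
        return SimulationConfig(**current)


@dataclass(frozen=True)
class GroundTruth:
    """True simulated quantities, for recovery tests only.

    Estimation code must never read these fields; they exist so that tests
    can compare estimates against the values the generator actually used.
    """

    mu: float
    gca_f: pd.Series
    gca_m: pd.Series
    sca: pd.DataFrame
    error: pd.DataFrame
    causal_markers: tuple[str, ...]
    marker_effects_f: pd.Series
    marker_effects_m: pd.Series
    variance_components: dict[str, float]
    heritability: float


@dataclass
class SyntheticDataset:
    """One simulated factorial: predictors, phenotypes and ground truth."""

    config: SimulationConfig
    pools: PoolAssignment
    markers: pd.DataFrame            # lines x markers, {0.0, 1.0, NaN}
    expression: pd.DataFrame         # lines x genes, linear-scale line means
    expression_replicates: pd.DataFrame  # (line, replicate) x genes, linear scale
    hybrids: pd.DataFrame            # columns: female, male, value
    per_se: pd.Series                # per-line inbred performance
    truth: GroundTruth = field(repr=False, default=None)


def _scaled_to_variance(values: np.ndarray, target_var: float, rng: np.random.Generator) -> np.ndarray:
    """Center values and rescale so their sample variance equals target_var."""
    if target_var == 0.0:
        return np.zeros_like(values)
    centered = values - values.mean()
    sd = centered.std(ddof=1)
    if sd == 0.0:
        # degenerate causal states (e.g. monomorphic draw); fall back to
        # exchangeable Gaussian line effects so the variance target is met
        centered = rng.standard_normal(values.shape)
        centered -= centered.mean()
        sd = centered.std(ddof=1)
    return centered * (np.sqrt(target_var) / sd)


def simulate_factorial(config: SimulationConfig) -> SyntheticDataset:
    """Generate a complete factorial dataset from ``config``.

    Fully reproducible: identical configs (including ``seed``) yield
    bitwise-identical datasets.
    """
    rng = np.random.default_rng(config.seed)
    nf, nm = config.n_female_lines, config.n_male_lines
    female = tuple(f"F{i + 1:02d}" for i in range(nf))
    male = tuple(f"D{i + 1:02d}" for i in range(nm))
    pools = PoolAssignment(female, male)
    marker_ids = [f"mk{j + 1:04d}" for j in range(config.n_markers)]
    gene_ids = [f"gene{j + 1:05d}" for j in range(config.n_transcripts)]

    # dominant marker states with pool-specific band frequencies
    lo, hi = config.band_freq_range
    freq_f = rng.uniform(lo, hi, size=config.n_markers)
    freq_m = rng.uniform(lo, hi, size=config.n_markers)
    states_f = (rng.random((nf, config.n_markers)) < freq_f).astype(float)
    states_m = (rng.random((nm, config.n_markers)) < freq_m).astype(float)

    causal_idx = np.sort(rng.choice(config.n_markers, size=config.n_causal, replace=False))
    eff_f = rng.standard_normal(config.n_causal)
    eff_m = rng.standard_normal(config.n_causal)

    g_f = _scaled_to_variance(states_f[:, causal_idx] @ eff_f, config.var_gca_f, rng)
    g_m = _scaled_to_variance(states_m[:, causal_idx] @ eff_m, config.var_gca_m, rng)

    sca = rng.normal(0.0, np.sqrt(config.var_sca), size=(nf, nm))
    err = rng.normal(0.0, np.sqrt(config.var_error), size=(nf, nm))
    mu = config.mean_phenotype
    y = mu + g_f[:, None] + g_m[None, :] + sca + err

    records = [
        (female[i], male[j], y[i, j]) for i in range(nf) for j in range(nm)
    ]
    hybrids = pd.DataFrame(records, columns=["female", "male", "value"])

    # per-se inbred performance: depressed mean plus a partial reflection
    # of the line's GCA (coefficient < 2 leaves a predictor-linked share
    # of each GCA inside the heterosis, as dominance does in real data)
    g_all = np.concatenate([g_f, g_m])
    per_se_vals = (
        mu
        - config.per_se_depression
        + config.per_se_gca_coef * g_all
        + rng.normal(0.0, np.sqrt(config.var_error), size=nf + nm)
    )
    per_se = pd.Series(per_se_vals, index=list(female) + list(male), name="per_se")

    # transcript line means on log2 scale, linked to causal marker states
    states_all = np.vstack([states_f, states_m])
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=config.n_transcripts)
    linkage = rng.random((config.n_causal, config.n_transcripts)) < config.transcript_linkage_density
    loadings = linkage * rng.normal(0.0, config.transcript_effect_sd, size=linkage.shape)
    log2_means = baseline[None, :] + (states_all[:, causal_idx] - 0.5) @ loadings

    reps = config.replicates_per_line
    rep_noise = rng.normal(0.0, config.transcript_noise_sd, size=(len(states_all) * reps, config.n_transcripts))
    rep_log2 = np.repeat(log2_means, reps, axis=0) + rep_noise
    rep_index = pd.MultiIndex.from_product(
        [list(female) + list(male), range(1, reps + 1)], names=["line", "replicate"]
    )
    expression_replicates = pd.DataFrame(
        np.exp2(rep_log2), index=rep_index, columns=gene_ids
    )
    expression = pd.DataFrame(
        np.exp2(log2_means), index=list(female) + list(male), columns=gene_ids
    )

    marker_values = np.vstack([states_f, states_m])
    if config.missing_marker_rate > 0:
        mask = rng.random(marker_values.shape) < config.missing_marker_rate
        marker_values = marker_values.copy()
        marker_values[mask] = np.nan
    markers = pd.DataFrame(marker_values, index=list(female) + list(male), columns=marker_ids)

    truth = GroundTruth(
        mu=mu,
        gca_f=pd.Series(g_f, index=list(female)),
        gca_m=pd.Series(g_m, index=list(male)),
        sca=pd.DataFrame(sca, index=list(female), columns=list(male)),
        error=pd.DataFrame(err, index=list(female), columns=list(male)),
        causal_markers=tuple(marker_ids[j] for j in causal_idx),
        marker_effects_f=pd.Series(eff_f, index=[marker_ids[j] for j in causal_idx]),
        marker_effects_m=pd.Series(eff_m, index=[marker_ids[j] for j in causal_idx]),
        variance_components={
            "var_gca_f": config.var_gca_f,
            "var_gca_m": config.var_gca_m,
            "var_sca": config.var_sca,
            "var_error": config.var_error,
        },
        heritability=config.heritability,
    )

    return SyntheticDataset(
        config=config,
        pools=pools,
        markers=markers,
        expression=expression,
        expression_replicates=expression_replicates,
        hybrids=hybrids,
        per_se=per_se,
        truth=truth,
    )


def mid_parent_heterosis(hybrids: pd.DataFrame, per_se) -> pd.DataFrame:
    """Attach a mid-parent heterosis (MPH) column to a hybrid table.

    MPH_fm = y_fm - (P_f + P_m) / 2, the excess of the hybrid over the
    mean of its parents' inbred per-se performance.  The original
    phenotype column is retained.
    """
    per_se = pd.Series(per_se)
    parents = set(hybrids["female"]) | set(hybrids["male"])
    missing = sorted(parents - set(per_se.index))
    if missing:
        raise DataError(f"no per-se value for parental line(s): {missing}")
    out = hybrids.copy()
    mid_parent = (
        per_se.loc[out["female"]].to_numpy() + per_se.loc[out["male"]].to_numpy()
    ) / 2.0
    out["mph"] = out["value"].to_numpy() - mid_parent
    return out
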