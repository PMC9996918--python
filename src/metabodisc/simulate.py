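"""Synthetic peak-intensity tables with known ground truth.

Emulates the statistical structure of an untargeted LC-MS metabolomics
experiment contrasting two divergently selected populations: two balanced
groups of animals, a few hundred metabolites with log-normal peak areas,
heterogeneous per-metabolite dispersion, a configurable subset of metabolites
carrying true between-population shifts stated in within-group SD units, and
left-censored (below-detection) missingness applied per acquisition method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import GroundTruth, PeakTable
from .errors import ConfigError

#: Labels for the four UPLC-MS/MS acquisition methods of a Metabolon-style
#: platform; generic labels are used for any other method count.
_FOUR_METHODS = ("RP_pos_hydrophilic", "RP_pos_hydrophobic", "RP_neg", "HILIC_neg")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic two-population experiment.

    Defaults mirror the study design this generator emulates: 13 animals per
    population, ~200 metabolites on four acquisition methods, 10 metabolites
    with a 2-SD shift, and ~10% below-detection censoring.
    """

    n_per_group: int = 13
    n_metabolites: int = 200
    n_informative: int = 10
    effect_sd: float | Sequence[float] = 2.0
    n_methods: int = 4
    missing_rate: float = 0.10
    base_log_mean: float = 15.0
    base_log_sd: float = 0.6
    seed: int | None = None

    def validate(self) -> None:
        if self.n_per_group < 3:
            raise ConfigError(f"n_per_group must be >= 3, got {self.n_per_group}")
        if self.n_metabolites < 2:
            raise ConfigError(f"n_metabolites must be >= 2, got {self.n_metabolites}")
        if not 0 <= self.n_informative <= self.n_metabolites:
            raise ConfigError(
                f"n_informative must lie in [0, n_metabolites], got {self.n_informative}"
            )
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError(f"missing_rate must lie in [0, 1), got {self.missing_rate}")
        if self.n_methods < 1:
            raise ConfigError(f"n_methods must be >= 1, got {self.n_methods}")
        if self.base_log_sd <= 0:
            raise ConfigError(f"base_log_sd must be > 0, got {self.base_log_sd}")
        effects = self._effect_array()
        if not np.all(np.isfinite(effects)):
            raise ConfigError("effect_sd must be finite")

    def _effect_array(self) -> np.ndarray:
        """Per-informative-metabolite effect magnitudes, length n_informative."""
        if np.isscalar(self.effect_sd):
            return np.full(self.n_informative, float(self.effect_sd))
        arr = np.asarray(self.effect_sd, dtype=float)
        if arr.shape != (self.n_informative,):
            raise ConfigError(
                f"effect_sd list must have length n_informative={self.n_informative}, "
                f"got {arr.shape}"
            )
        return arr

    def method_labels(self) -> list[str]:
        if self.n_methods == 4:
            return list(_FOUR_METHODS)
        return [f"method_{i + 1}" for i in range(self.n_methods)]


def generate_dataset(config: SimulationConfig) -> tuple[PeakTable, GroundTruth]:
    """Draw a complete (no-missing) peak table plus its ground truth.

    Per metabolite j, log-intensities are Normal(mu_j, sigma_j^2) with
    mu_j ~ Normal(base_log_mean, 1) and sigma_j ~ Uniform(0.5, 1.5) ×
    base_log_sd, mimicking the wide dispersion range of untargeted peak
    areas.  Informative metabolites have their group log-means separated by
    effect_sd × sigma_j (additive on the log scale, sign random), so the true
    standardized difference H − L equals the signed configured effect.
    Metabolites are assigned round-robin to the acquisition methods.
    Identical seeds give bit-identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_half, p = config.n_per_group, config.n_metabolites
    n = 2 * n_half

    met_ids = [f"M{j + 1:04d}" for j in range(p)]
    sample_ids = [f"L{i + 1:02d}" for i in range(n_half)] + [
        f"H{i + 1:02d}" for i in range(n_half)
    ]
    population = pd.Series(["L"] * n_half + ["H"] * n_half, index=sample_ids, name="population")

    mu = rng.normal(config.base_log_mean, 1.0, size=p)
    sigma = config.base_log_sd * rng.uniform(0.5, 1.5, size=p)

    effects = np.zeros(p)
    if config.n_informative:
        idx = rng.choice(p, size=config.n_informative, replace=False)
        signs = rng.choice([-1.0, 1.0], size=config.n_informative)
        effects[idx] = config._effect_array() * signs

    log_x = mu + sigma * rng.standard_normal(size=(n, p))
    # split the H − L separation symmetrically around mu
    half_shift = 0.5 * effects * sigma
    is_h = (population == "H").to_numpy()
    log_x[is_h] += half_shift
    log_x[~is_h] -= half_shift

    values = pd.DataFrame(np.exp(log_x), index=sample_ids, columns=met_ids)
    labels = config.method_labels()
    method_of = pd.Series(
        [labels[j % config.n_methods] for j in range(p)], index=met_ids, name="method"
    )
    table = PeakTable(values=values, population=population, method_of=method_of)
    truth = GroundTruth(true_effects=pd.Series(effects, index=met_ids, name="true_effect"))
    return table, truth


def inject_missingness(table: PeakTable, config: SimulationConfig) -> PeakTable:
    """Left-censor the table: per acquisition method, entries below the
    ``missing_rate`` intensity quantile become missing.

    Censoring is deterministic given the table (a threshold at a quantile),
    so every hidden value is at most every observed value of the same method
    and the achieved missing fraction tracks the target.  The pre-censoring
    values are retained on the returned table (``hidden_values``) for
    oracle checks.
    """
    if not 0.0 <= config.missing_rate < 1.0:
        raise ConfigError(f"missing_rate must lie in [0, 1), got {config.missing_rate}")
    out = table.copy()
    out.hidden_values = table.values.copy()
    if config.missing_rate == 0.0:
        return out
    values = out.values
    for method in out.method_of.unique():
        cols = out.method_of.index[out.method_of == method]
        block = values[cols].to_numpy()
        threshold = np.quantile(block, config.missing_rate)
        values[cols] = values[cols].mask(values[cols] < threshold)
    return out
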