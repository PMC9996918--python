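"""In-memory containers passed between pipeline stages.

A :class:`PeakTable` holds a samples × metabolites matrix of raw peak areas
(positive reals, ``NaN`` marking below-detection entries), per-sample
population labels and the metabolite → acquisition-method map.  A
:class:`TransformedMatrix` is the analysis-ready ALR-then-autoscaled matrix
with provenance (reference metabolite, pre-scaling column statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

#: The two-population vocabulary: L = resilient (low V_E of litter size),
#: H = non-resilient (high V_E).
POPULATIONS = ("H", "L")

#: The class treated as "positive" in accuracy/precision (resilient line).
POSITIVE_CLASS = "L"


@dataclass
class PeakTable:
    """Raw peak-intensity table with population and acquisition-method labels.

    Parameters
    ----------
    values
        Samples × metabolites peak areas; ``NaN`` encodes a missing
        (below-detection) entry.  Observed entries must be strictly positive.
    population
        Per-sample label, one of ``{"H", "L"}``, indexed like ``values`` rows.
    method_of
        Metabolite → acquisition-method label, indexed like ``values`` columns.
    hidden_values
        Pre-censoring values kept by the simulator so censoring can be checked
        against ground truth; ``None`` for real data.
    """

    values: pd.DataFrame
    population: pd.Series
    method_of: pd.Series
    hidden_values: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.population.index):
            missing = self.values.index.difference(self.population.index)
            if len(missing):
                raise InputError(f"samples without a population label: {list(missing)[:5]}")
            self.population = self.population.reindex(self.values.index)
        unlabeled = set(self.values.columns) - set(self.method_of.index)
        if unlabeled:
            raise InputError(f"metabolites without a method label: {sorted(unlabeled)[:5]}")
        self.method_of = self.method_of.reindex(self.values.columns)
        bad = self.population[~self.population.isin(POPULATIONS)]
        if len(bad):
            raise InputError(
                f"population labels must be in {POPULATIONS}; offending samples: "
                f"{list(bad.index)[:5]}"
            )
        vals = self.values.to_numpy(dtype=float)
        observed = ~np.isnan(vals)
        if not (vals[observed] > 0).all():
            raise InputError("observed peak intensities must be strictly positive")

    # -- convenience views -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean mask, True where an entry is missing."""
        return self.values.isna()

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "PeakTable":
        return PeakTable(
            values=self.values.copy(),
            population=self.population.copy(),
            method_of=self.method_of.copy(),
            hidden_values=None if self.hidden_values is None else self.hidden_values.copy(),
        )


@dataclass
class TransformedMatrix:
    """ALR-transformed, autoscaled abundance matrix (samples × p−1).

    ``column_means``/``column_sds`` are the pre-scaling ALR statistics, so the
    transform can be inverted exactly; ``reference_id`` is the ALR denominator
    metabolite (absent from the columns).
    """

    values: pd.DataFrame
    reference_id: str | None
    column_means: pd.Series
    column_sds: pd.Series
    population: pd.Series

    def __post_init__(self) -> None:
        if self.reference_id is not None and self.reference_id in self.values.columns:
            raise InputError("reference metabolite must not appear among ALR columns")

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.columns)

    def unscale(self) -> pd.DataFrame:
        """Invert autoscaling, recovering the raw ALR matrix."""
        return self.values.mul(self.column_sds, axis=1).add(self.column_means, axis=1)


@dataclass
class GroundTruth:
    """True per-metabolite between-population shifts, in SD units (H − L)."""

    true_effects: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    @property
    def informative_ids(self) -> list[str]:
        return list(self.true_effects.index[self.true_effects != 0.0])
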