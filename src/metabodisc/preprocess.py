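"""Raw peak table → analysis-ready matrix.

Pipeline: drop metabolites with excess missingness in either population,
impute remaining missing entries with half the per-acquisition-method minimum,
map to unconstrained space with the additive log-ratio (ALR) transform against
the lowest-CV reference metabolite, check near-isometry of that choice with a
Procrustes correlation against the centered log-ratio (CLR) geometry, and
autoscale columns to mean 0 / SD 1.

Peak tables are compositional: only relative information is meaningful, which
is why all contrasts run on log-ratios rather than raw areas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import procrustes as _scipy_procrustes

from .containers import PeakTable, TransformedMatrix
from .errors import ImputationError, InputError, ScalingError

logger = logging.getLogger(__name__)

DEFAULT_MISSING_THRESHOLD = 0.20


def filter_missing(table: PeakTable, threshold: float = DEFAULT_MISSING_THRESHOLD) -> PeakTable:
    """Remove metabolites whose missing fraction exceeds ``threshold`` in at
    least one population.

    A metabolite that is largely unobserved in either population cannot
    support a two-group contrast, so exceedance in a single population is
    already disqualifying.
    """
    if not 0.0 < threshold < 1.0:
        raise InputError(f"threshold must lie in (0, 1), got {threshold}")
    present = set(table.population.unique())
    absent = {"H", "L"} - present
    if absent:
        raise InputError(f"population(s) with zero samples: {sorted(absent)}")
    mask = table.missing_mask
    drop = pd.Series(False, index=table.values.columns)
    for pop in table.population.unique():
        rows = table.population == pop
        if rows.sum() == 0:
            raise InputError(f"population {pop!r} has zero samples")
        drop |= mask.loc[rows.to_numpy()].mean(axis=0) > threshold
    kept = [m for m in table.metabolite_ids if not drop[m]]
    logger.info(
        "filter_missing: removed %d of %d metabolites (>%.0f%% missing in a population)",
        int(drop.sum()), table.n_metabolites, 100 * threshold,
    )
    return PeakTable(
        values=table.values[kept].copy(),
        population=table.population.copy(),
        method_of=table.method_of.reindex(kept),
        hidden_values=None if table.hidden_values is None else table.hidden_values[kept].copy(),
    )


def impute_half_min(table: PeakTable) -> PeakTable:
    """Replace each missing entry with half the minimum observed intensity of
    the acquisition method its metabolite belongs to.

    The minimum is method-wide — over all metabolites and samples measured by
    that method — which treats the method's smallest observed peak as its
    effective detection floor.
    """
    values = table.values.copy()
    for method in table.method_of.unique():
        cols = table.method_of.index[table.method_of == method]
        block = values[cols]
        if not block.notna().to_numpy().any():
            raise ImputationError(f"method {method!r} has no observed values to impute from")
        fill = 0.5 * np.nanmin(block.to_numpy())
        values[cols] = block.fillna(fill)
    return PeakTable(
        values=values,
        population=table.population.copy(),
        method_of=table.method_of.copy(),
    )


def select_alr_reference(table: PeakTable) -> str:
    """Pick the ALR reference: the metabolite with the lowest coefficient of
    variation (SD/mean of raw post-imputation intensities, all samples).

    Ties break toward the earlier column for determinism.
    """
    if table.missing_mask.to_numpy().any():
        raise InputError("reference selection requires a complete (imputed) table")
    if table.n_metabolites < 2:
        raise InputError("need at least 2 metabolites to pick an ALR reference")
    means = table.values.mean(axis=0)
    if (means == 0).any():
        raise InputError("coefficient of variation undefined: a metabolite has mean 0")
    cv = table.values.std(axis=0, ddof=1) / means
    ref = cv.idxmin()  # first occurrence wins on ties
    logger.info("ALR reference: %s (CV=%.4g)", ref, cv[ref])
    return str(ref)


def alr_transform(table: PeakTable, reference_id: str) -> pd.DataFrame:
    """Additive log-ratio transform: column j becomes ln(x_j) − ln(x_ref).

    The reference column is dropped, so p metabolites yield p−1 ALR
    coordinates.  Ratios make the result invariant to per-sample
    multiplicative scaling (the compositional contract).
    """
    if reference_id not in table.values.columns:
        raise InputError(f"reference metabolite {reference_id!r} not in table")
    if table.missing_mask.to_numpy().any():
        raise InputError("ALR transform requires a complete (imputed) table")
    vals = table.values.to_numpy(dtype=float)
    if not (vals > 0).all():
        i, j = np.argwhere(~(vals > 0))[0]
        raise InputError(
            f"nonpositive intensity at sample {table.sample_ids[i]!r}, "
            f"metabolite {table.metabolite_ids[j]!r}"
        )
    logs = np.log(table.values)
    alr = logs.sub(logs[reference_id], axis=0).drop(columns=reference_id)
    return alr


def _principal_coordinates(x: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Centered configuration rotated to its principal axes (PCA scores),
    keeping components with non-negligible singular values."""
    xc = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    keep = s > tol * max(s[0], 1.0)
    return u[:, keep] * s[keep]


def procrustes_check(alr: pd.DataFrame, table: PeakTable) -> float:
    """Procrustes correlation between the ALR sample configuration and the
    CLR (isometric reference geometry) configuration of the same table.

    Both configurations are reduced to principal coordinates and superimposed
    under translation, rotation and uniform scaling; the statistic is
    sqrt(1 − m²) with m² the minimized standardized Procrustes sum of
    squares.  Values near 1 mean the ALR choice of reference distorts the
    compositional geometry little.  Reported, not enforced.
    """
    if alr.shape[0] != table.n_samples:
        raise InputError(
            f"sample count mismatch: ALR has {alr.shape[0]}, table has {table.n_samples}"
        )
    logs = np.log(table.values.to_numpy(dtype=float))
    clr = logs - logs.mean(axis=1, keepdims=True)
    a = _principal_coordinates(alr.to_numpy(dtype=float))
    b = _principal_coordinates(clr)
    k = min(a.shape[1], b.shape[1])
    _, _, disparity = _scipy_procrustes(b[:, :k], a[:, :k])
    return float(np.sqrt(max(0.0, 1.0 - disparity)))


def autoscale(
    matrix: pd.DataFrame,
    population: pd.Series | None = None,
    reference_id: str | None = None,
) -> TransformedMatrix:
    """Center each column and divide by its sample SD (n−1 denominator).

    The pre-scaling means/SDs ride along so the transform round-trips
    exactly; downstream effect sizes are thereby in per-metabolite SD units.
    """
    if matrix.shape[0] < 2:
        raise InputError("autoscaling needs at least 2 samples")
    means = matrix.mean(axis=0)
    sds = matrix.std(axis=0, ddof=1)
    flat = sds[sds == 0]
    if len(flat):
        raise ScalingError(f"constant column(s) cannot be autoscaled: {list(flat.index)[:5]}")
    scaled = matrix.sub(means, axis=1).div(sds, axis=1)
    if population is None:
        population = pd.Series(index=matrix.index, dtype=object)
    return TransformedMatrix(
        values=scaled,
        reference_id=reference_id,
        column_means=means,
        column_sds=sds,
        population=population.reindex(matrix.index),
    )


@dataclass
class PreprocessResult:
    """Analysis-ready matrix plus a provenance report."""

    matrix: TransformedMatrix
    report: dict


def preprocess_table(
    table: PeakTable,
    missing_threshold: float = DEFAULT_MISSING_THRESHOLD,
    procrustes_warn: float = 0.95,
) -> PreprocessResult:
    """Full chain: filter → impute → select reference → ALR → Procrustes
    check → autoscale.  Sample count and order are preserved throughout."""
    filtered = filter_missing(table, missing_threshold)
    imputed = impute_half_min(filtered)
    reference = select_alr_reference(imputed)
    alr = alr_transform(imputed, reference)
    r = procrustes_check(alr, imputed)
    if r < procrustes_warn:
        logger.warning(
            "Procrustes correlation %.4f below %.2f: ALR reference may distort geometry",
            r, procrustes_warn,
        )
    matrix = autoscale(alr, population=table.population, reference_id=reference)
    report = {
        "n_metabolites_in": table.n_metabolites,
        "n_removed_missing": table.n_metabolites - filtered.n_metabolites,
        "n_retained": filtered.n_metabolites,
        "n_alr_columns": matrix.values.shape[1],
        "reference_id": reference,
        "procrustes_correlation": r,
        "missing_threshold": missing_threshold,
    }
    return PreprocessResult(matrix=matrix, report=report)
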