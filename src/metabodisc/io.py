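"""TSV/JSON readers and writers for the pipeline's tables.

Peak tables are plain TSV: first column sample id, second column population
label, remaining columns metabolite intensities with missing entries left
empty.  A companion two-column TSV maps metabolite id → acquisition method.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .containers import GroundTruth, PeakTable, TransformedMatrix
from .errors import InputError


def write_peak_table(table: PeakTable, path: str | Path, sep: str = "\t") -> None:
    df = table.values.copy()
    df.insert(0, "population", table.population)
    df.to_csv(path, sep=sep, index_label="sample")


def write_methods(method_of: pd.Series, path: str | Path, sep: str = "\t") -> None:
    method_of.rename("method").to_csv(path, sep=sep, index_label="metabolite")


def read_peak_table(
    values_path: str | Path, methods_path: str | Path, sep: str = "\t"
) -> PeakTable:
    df = pd.read_csv(values_path, sep=sep, index_col=0)
    if "population" not in df.columns:
        raise InputError(f"{values_path}: expected a 'population' column")
    population = df.pop("population").astype(str)
    methods = pd.read_csv(methods_path, sep=sep, index_col=0)["method"].astype(str)
    return PeakTable(
        values=df.astype(float), population=population, method_of=methods
    )


def write_ground_truth(truth: GroundTruth, path: str | Path, sep: str = "\t") -> None:
    truth.true_effects.rename("true_effect").to_csv(path, sep=sep, index_label="metabolite")


def read_ground_truth(path: str | Path, sep: str = "\t") -> GroundTruth:
    s = pd.read_csv(path, sep=sep, index_col=0)["true_effect"].astype(float)
    return GroundTruth(true_effects=s)


def write_transformed(matrix: TransformedMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write the autoscaled matrix as TSV plus a JSON sidecar with provenance
    (reference metabolite, pre-scaling column means/SDs)."""
    df = matrix.values.copy()
    df.insert(0, "population", matrix.population)
    df.to_csv(path, sep=sep, index_label="sample")
    meta = {
        "reference_id": matrix.reference_id,
        "column_means": matrix.column_means.to_dict(),
        "column_sds": matrix.column_sds.to_dict(),
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_transformed(path: str | Path, sep: str = "\t") -> TransformedMatrix:
    df = pd.read_csv(path, sep=sep, index_col=0)
    if "population" not in df.columns:
        raise InputError(f"{path}: expected a 'population' column")
    population = df.pop("population").astype(str)
    meta_path = Path(str(path) + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        reference = meta.get("reference_id")
        means = pd.Series(meta["column_means"]).reindex(df.columns)
        sds = pd.Series(meta["column_sds"]).reindex(df.columns)
    else:
        reference = None
        means = pd.Series(0.0, index=df.columns)
        sds = pd.Series(1.0, index=df.columns)
    return TransformedMatrix(
        values=df.astype(float), reference_id=reference,
        column_means=means, column_sds=sds, population=population,
    )
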