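"""Counting statistics of the cell-counting assay.

Event counts are normalized to a 1 mL volume; the count threshold above
which a sample is declared positive is the mean of the worst (highest-count)
negative control plus three times its standard deviation.  Standard
deviations throughout use the population convention (divisor n) — the only
convention that reproduces the published summary statistics of the packaged
count matrix.  ELISA-style blank-based limits of detection / quantification
(blank mean + 3 SD / + 10 SD) are provided for comparison with plate assays.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "ThresholdResult",
    "load_reference_counts",
    "normalize_counts",
    "detection_count_threshold",
    "summarize_table",
    "table_threshold",
    "classify_and_bracket_lod",
    "blank_based_lod_loq",
    "population_sd",
]


def population_sd(values: Sequence[float]) -> float:
    """Standard deviation with divisor n."""
    return float(np.std(np.asarray(values, dtype=float), ddof=0))


@dataclass
class CountTable:
    """Per-sample replicate counts (per mL) with class labels.

    ``rows`` is a DataFrame with columns ``sample_label``, ``nominal_class``
    ('positive'/'negative'), ``concentration_per_mL`` (NaN for negatives)
    and ``counts_per_mL`` (list of replicate counts).
    """

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_label", "nominal_class", "concentration_per_mL", "counts_per_mL"}
        missing = required - set(self.rows.columns)
        if missing:
            raise ValueError(f"count table is missing columns: {sorted(missing)}")
        if not (self.rows["nominal_class"] == "negative").any():
            raise ValueError("count table needs at least one negative row for thresholding")
        for counts in self.rows["counts_per_mL"]:
            if any(c < 0 for c in counts):
                raise ValueError("counts must be non-negative")

    @property
    def negatives(self) -> pd.DataFrame:
        return self.rows[self.rows["nominal_class"] == "negative"]

    @property
    def positives(self) -> pd.DataFrame:
        return self.rows[self.rows["nominal_class"] == "positive"]


def load_reference_counts() -> CountTable:
    """Load the packaged per-mL count matrix of the seven-experiment study."""
    with resources.files("gmrcyto.data").joinpath("table2_counts.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["counts_per_mL"] = df["counts_per_mL"].apply(
        lambda s: [float(x) for x in str(s).split(",")]
    )
    df["concentration_per_mL"] = pd.to_numeric(df["concentration_per_mL"], errors="coerce")
    return CountTable(df)


def normalize_counts(event_count: float, volume_mL: float) -> float:
    """Counts per milliliter from a raw event count and the assayed volume."""
    if volume_mL <= 0:
        raise ValueError("volume must be positive")
    return event_count / volume_mL


@dataclass(frozen=True)
class ThresholdResult:
    """Mean + 3 SD decision threshold derived from negative-control counts."""

    negative_mean: float
    negative_sd: float
    count_threshold: float


def detection_count_threshold(negative_counts: Sequence[float]) -> ThresholdResult:
    """Count threshold = mean + 3 x population SD of negative-control counts."""
    vals = np.asarray(negative_counts, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least two negative-control values")
    mean = float(vals.mean())
    sd = population_sd(vals)
    return ThresholdResult(mean, sd, mean + 3.0 * sd)


def summarize_table(table: CountTable) -> pd.DataFrame:
    """Per-row mean and population SD of the replicate counts."""
    if table.rows.empty:
        raise ValueError("count table is empty")
    out = table.rows.copy()
    out["mean"] = out["counts_per_mL"].apply(lambda c: float(np.mean(c)))
    out["sd"] = out["counts_per_mL"].apply(population_sd)
    out["n_replicates"] = out["counts_per_mL"].apply(len)
    return out[
        ["sample_label", "nominal_class", "concentration_per_mL", "n_replicates", "mean", "sd"]
    ]


def table_threshold(table: CountTable) -> ThresholdResult:
    """Threshold from the negative control with the highest mean count."""
    summary = summarize_table(table)
    negs = summary[summary["nominal_class"] == "negative"]
    worst_label = negs.loc[negs["mean"].idxmax(), "sample_label"]
    counts = table.rows.loc[table.rows["sample_label"] == worst_label, "counts_per_mL"].iloc[0]
    return detection_count_threshold(counts)


def classify_and_bracket_lod(
    table: CountTable,
    threshold: float,
) -> tuple[pd.DataFrame, tuple[Optional[float], Optional[float]], bool]:
    """Per-sample verdicts and the concentration bracket containing the LOD.

    A positive-composition row is declared positive when its mean count
    exceeds the threshold.  The bracket is (highest concentration declared
    negative, lowest concentration declared positive); an open upper end is
    flagged when no positive row exceeds the threshold.
    """
    summary = summarize_table(table)
    verdicts = summary.copy()
    verdicts["verdict_positive"] = verdicts["mean"] > threshold
    pos = verdicts[verdicts["nominal_class"] == "positive"].dropna(
        subset=["concentration_per_mL"]
    )
    if pos.empty:
        raise ValueError("no positive rows with nominal concentrations")
    declared_pos = pos[pos["verdict_positive"]]
    declared_neg = pos[~pos["verdict_positive"]]
    upper = float(declared_pos["concentration_per_mL"].min()) if not declared_pos.empty else None
    lower = float(declared_neg["concentration_per_mL"].max()) if not declared_neg.empty else None
    open_bracket = upper is None
    return verdicts, (lower, upper), open_bracket


def blank_based_lod_loq(blank_values: Sequence[float]) -> tuple[float, float]:
    """Plate-assay limits: (blank mean + 3 SD, blank mean + 10 SD)."""
    vals = np.asarray(blank_values, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least two blank measurements")
    mean = float(vals.mean())
    sd = population_sd(vals)
    return mean + 3.0 * sd, mean + 10.0 * sd
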