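"""Per-chip and per-probe normalization of single-channel intensity data.

Two steps, in the order array-analysis suites apply them: a per-sample
percentile shift (each chip's chosen percentile, by default the 75th, is
subtracted from every probe on that chip, removing array-level scaling
offsets) followed by a per-probe baseline transformation to the median of
all samples (each probe row is centred on its cross-sample median, so
values express deviation from the probe's typical signal).

All operations work on log2 intensities held in a pandas DataFrame of shape
(probes × samples).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

GENOTYPES = ("tolerant", "sensitive")
ORGANS = ("leaf", "root")
CONDITIONS = ("control", "drought")

SAMPLE_SHEET_COLUMNS = ("sample_id", "genotype", "organ", "condition", "replicate")


class IngestionError(ValueError):
    """Raised when an input matrix contains entries that cannot be analysed."""


def log2_transform(raw: pd.DataFrame, floor: float = 1.0) -> pd.DataFrame:
    """Log2-transform a linear-scale intensity matrix with a detection floor.

    Parameters
    ----------
    raw
        Linear-scale intensities, probes × samples. All entries must be finite.
    floor
        Positive linear value; intensities below it are clipped up to it
        before taking log2, so the output is bounded below by ``log2(floor)``.

    Returns
    -------
    DataFrame of log2 intensities with the same index/columns.
    """
    if floor <= 0:
        raise ValueError(f"floor must be positive, got {floor}")
    values = raw.to_numpy(dtype=float)
    bad = ~np.isfinite(values)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise IngestionError(
            f"non-finite intensity at probe {raw.index[i]!r}, sample {raw.columns[j]!r}"
        )
    return pd.DataFrame(
        np.log2(np.maximum(values, floor)), index=raw.index, columns=raw.columns
    )


def percentile_shift(
    matrix: pd.DataFrame, percentile: float = 75.0
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-chip percentile-shift normalization.

    For every sample column the requested percentile of that column
    (linear interpolation between closest ranks, r = 1 + q(n−1)) is
    subtracted from all entries, so the percentile of each output column is
    exactly zero. Removes any additive per-array offset on the log2 scale
    (multiplicative on the linear scale).

    Returns the shifted matrix and the per-sample shift that was applied.
    """
    if matrix.shape[1] == 0 or matrix.shape[0] < 2:
        raise ValueError("percentile_shift needs at least 2 probes per sample column")
    if not 0 <= percentile <= 100:
        raise ValueError(f"percentile must be in [0, 100], got {percentile}")
    shifts = pd.Series(
        np.percentile(matrix.to_numpy(dtype=float), percentile, axis=0),
        index=matrix.columns,
        name="shift",
    )
    return matrix.sub(shifts, axis=1), shifts


def baseline_to_median(matrix: pd.DataFrame) -> pd.DataFrame:
    """Baseline transformation: centre each probe row on its median across
    *all* samples (both organs, both genotypes, both conditions), so every
    output row has median exactly 0. Idempotent."""
    medians = matrix.median(axis=1)
    return matrix.sub(medians, axis=0)


def normalize_matrix(
    raw: pd.DataFrame, floor: float = 1.0, percentile: float = 75.0
) -> tuple[pd.DataFrame, pd.Series]:
    """Full ingestion path: log2 → percentile shift → baseline to median.

    Returns the normalized matrix and the per-sample shifts (the
    normalization log).
    """
    log2m = log2_transform(raw, floor=floor)
    shifted, shifts = percentile_shift(log2m, percentile=percentile)
    return baseline_to_median(shifted), shifts


def validate_sample_sheet(samples: pd.DataFrame, matrix: pd.DataFrame | None = None) -> pd.DataFrame:
    """Validate a sample sheet against the factor levels and, optionally,
    against a matrix's columns. Returns the sheet indexed by sample_id."""
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"sample sheet missing column(s): {missing}")
    if samples["sample_id"].duplicated().any():
        dup = samples.loc[samples["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id {dup!r} in sample sheet")
    for col, levels in (("genotype", GENOTYPES), ("organ", ORGANS), ("condition", CONDITIONS)):
        bad = set(samples[col]) - set(levels)
        if bad:
            raise ValueError(f"unknown {col} level(s) {sorted(bad)!r}; expected {levels}")
    sheet = samples.set_index("sample_id")
    if matrix is not None:
        uncovered = [c for c in matrix.columns if c not in sheet.index]
        if uncovered:
            raise ValueError(f"sample sheet does not cover matrix column(s): {uncovered}")
    return sheet
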