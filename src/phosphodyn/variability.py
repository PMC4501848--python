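"""Proteome-wide response magnitude over time.

The global effect of a stimulus is summarized as the width (interquartile
range) of the per-time-point log2 fold-change distribution across all
quantified peptides. Phosphopeptide IQR grows as the stimulus reshapes the
phosphoproteome, while nonphosphorylated-peptide IQR stays flat and
measures technical variability only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ParameterError
from .types import ProfileMatrix, ProteinAbundanceTrack


def iqr(values) -> float:
    """Q3 - Q1 with linear-interpolation quantiles.

    Uses the convention where the p-quantile of sorted x_1..x_n
    interpolates at rank 1 + (n-1)p (numpy's default 'linear' method).
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise InsufficientDataError(f"iqr needs >= 2 finite values, got {values.size}")
    q1, q3 = np.quantile(values, [0.25, 0.75], method="linear")
    return float(q3 - q1)


def variability_series(matrix: ProfileMatrix | list[ProteinAbundanceTrack],
                       peptide_class: str = "phospho",
                       stimulus: str | None = None) -> pd.DataFrame:
    """Per-time-point IQR of log2FC across profiles (or protein tracks).

    Returns a tidy frame with columns ``stimulus, peptide_class, time, n,
    iqr``; time points with fewer than two quantified values get NaN.
    """
    if peptide_class not in ("phospho", "nonphospho"):
        raise ParameterError(f"unknown peptide_class: {peptide_class!r}")

    if isinstance(matrix, ProfileMatrix):
        items = [(p.stimulus, p.times, p.log2fc) for p in matrix]
    else:
        items = [(t.stimulus, t.times, t.log2fc_series) for t in matrix]
    if not items:
        raise InsufficientDataError("empty profile collection")

    rows = []
    stimuli = sorted({s for s, _, _ in items}) if stimulus is None else [stimulus]
    for stim in stimuli:
        series = np.array([v for s, _, v in items if s == stim])
        times = next(t for s, t, _ in items if s == stim)
        for j, t in enumerate(times):
            col = series[:, j]
            col = col[np.isfinite(col)]
            value = iqr(col) if col.size >= 2 else np.nan
            rows.append((stim, peptide_class, float(t), int(col.size), value))
    return pd.DataFrame(rows, columns=["stimulus", "peptide_class", "time", "n", "iqr"])


def technical_cv(control_ratios) -> float:
    """Coefficient of variation (sample sd / mean) of linear ratios."""
    values = np.asarray(control_ratios, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise InsufficientDataError("technical_cv needs >= 2 values")
    if np.any(values <= 0):
        raise ParameterError("linear ratios must be positive")
    return float(np.std(values, ddof=1) / np.mean(values))
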