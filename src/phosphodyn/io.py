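"""Readers and writers for the tabular dialects the pipeline consumes.

Two site-table dialects are supported:

``simple``
    One row per (site, stimulus). Columns: ``site_id`` (``PROT_S123_m1``),
    ``stimulus`` (heat/cold), ``t0 .. t28`` (log2 fold change, blank =
    missing), optionally ``p0 .. p28`` (localization probabilities).
    Values are already on the log2 scale; the round trip through
    :func:`write_results` / :func:`read_site_table` is lossless.

``maxquant_sty``
    A MaxQuant "Phospho (STY)Sites"-style export: one row per site with
    ``Protein``, ``Position``, ``Amino acid``, optional ``Multiplicity``,
    and per-time-point *linear* SILAC ratio columns ``Ratio H/L <t>``
    (heat vs control) and ``Ratio M/L <t>`` (cold vs control), plus
    optional ``Localization prob <t>`` columns shared by both channels.
    Linear ratios are log2-transformed on ingest.

Unparseable or blank ratio cells become missing points; the reader never
invents values.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError
from .types import (
    TIME_GRID,
    KineticProfile,
    PhosphoSiteID,
    ProfileMatrix,
    ProteinAbundanceTrack,
)

_T_COLS = [f"t{int(t)}" for t in TIME_GRID]
_P_COLS = [f"p{int(t)}" for t in TIME_GRID]

_MQ_RATIO_COLS = {
    "heat": [f"Ratio H/L {int(t)}" for t in TIME_GRID],
    "cold": [f"Ratio M/L {int(t)}" for t in TIME_GRID],
}
_MQ_PROB_COLS = [f"Localization prob {int(t)}" for t in TIME_GRID]


def _parse_ratio_cell(cell) -> float:
    """A numeric cell or NaN; anything unparseable is a missing point."""
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return np.nan
    try:
        value = float(cell)
    except (TypeError, ValueError):
        return np.nan
    return value


def _require_columns(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")


def read_site_table(path, dialect: str = "simple") -> ProfileMatrix:
    """Read a phosphosite quantitation table into a :class:`ProfileMatrix`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if dialect == "simple":
        return _read_simple(df, path)
    if dialect == "maxquant_sty":
        return _read_maxquant(df, path)
    raise ParameterError(f"unknown dialect: {dialect!r}")


def _read_simple(df: pd.DataFrame, path) -> ProfileMatrix:
    _require_columns(df, ["site_id", "stimulus", *_T_COLS], path)
    has_probs = all(c in df.columns for c in _P_COLS)

    dupes = df[df.duplicated(subset=["site_id", "stimulus"], keep=False)]
    if len(dupes):
        keys = sorted({(r.site_id, r.stimulus) for r in dupes.itertuples()})
        raise FormatError(f"{path}: duplicate (site, stimulus) rows: {keys}")

    matrix = ProfileMatrix()
    for row in df.itertuples(index=False):
        log2fc = np.array([_parse_ratio_cell(getattr(row, c)) for c in _T_COLS])
        probs = None
        if has_probs:
            probs = np.array([_parse_ratio_cell(getattr(row, f"p{int(t)}")) for t in TIME_GRID])
        matrix.add(KineticProfile(
            site=PhosphoSiteID.parse(row.site_id),
            stimulus=row.stimulus,
            log2fc=log2fc,
            localization_probs=probs,
        ))
    return matrix


def _read_maxquant(df: pd.DataFrame, path) -> ProfileMatrix:
    _require_columns(df, ["Protein", "Position", "Amino acid"], path)
    channels = {
        stim: cols for stim, cols in _MQ_RATIO_COLS.items()
        if all(c in df.columns for c in cols)
    }
    if not channels:
        raise FormatError(
            f"{path}: missing mandatory column(s): {_MQ_RATIO_COLS['heat'][0]} "
            f"(no complete per-time ratio channel found)"
        )
    has_probs = all(c in df.columns for c in _MQ_PROB_COLS)

    matrix = ProfileMatrix()
    seen: set[tuple[str, str]] = set()
    duplicates: list[tuple[str, str]] = []
    for _, row in df.iterrows():
        if "Multiplicity" in df.columns and not pd.isna(row["Multiplicity"]):
            mult = int(float(row["Multiplicity"]))
        else:
            mult = 1
        site = PhosphoSiteID(
            protein=str(row["Protein"]),
            position=int(float(row["Position"])),
            residue=str(row["Amino acid"]),
            multiplicity=mult,
        )
        probs = None
        if has_probs:
            probs = np.array([_parse_ratio_cell(row[c]) for c in _MQ_PROB_COLS])
        for stim, cols in channels.items():
            linear = np.array([_parse_ratio_cell(row[c]) for c in cols])
            with np.errstate(divide="ignore", invalid="ignore"):
                log2fc = np.where(linear > 0, np.log2(np.where(linear > 0, linear, 1.0)), np.nan)
            key = (str(site), stim)
            if key in seen:
                duplicates.append(key)
                continue
            seen.add(key)
            matrix.add(KineticProfile(site=site, stimulus=stim, log2fc=log2fc,
                                      localization_probs=probs))
    if duplicates:
        raise FormatError(f"{path}: duplicate (site, stimulus) rows: {sorted(set(duplicates))}")
    return matrix


def localization_filter(matrix: ProfileMatrix, min_mean_prob: float = 0.75,
                        keep_unscored: bool = False) -> ProfileMatrix:
    """Retain profiles whose mean localization probability is >= threshold.

    The mean is taken over quantified points that carry a probability.
    Profiles with no probabilities at all are dropped by default
    (``keep_unscored=True`` retains them).
    """
    if not 0.0 <= min_mean_prob <= 1.0:
        raise ParameterError(f"min_mean_prob must lie in [0, 1], got {min_mean_prob}")
    out = ProfileMatrix(time_grid=matrix.time_grid)
    for profile in matrix:
        mean_prob = profile.mean_localization_prob()
        if np.isnan(mean_prob):
            if keep_unscored:
                out.add(profile)
            continue
        if mean_prob >= min_mean_prob:
            out.add(profile)
    return out


def read_protein_quant(path) -> list[ProteinAbundanceTrack]:
    """Read the nonphosphopeptide protein quantitation table.

    Columns: ``protein``, ``stimulus``, ``t0 .. t28`` holding *linear*
    stimulus/control ratios; log2-transformed on ingest.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["protein", "stimulus", *_T_COLS], path)
    dupes = df[df.duplicated(subset=["protein", "stimulus"], keep=False)]
    if len(dupes):
        keys = sorted({(r.protein, r.stimulus) for r in dupes.itertuples()})
        raise FormatError(f"{path}: duplicate (protein, stimulus) rows: {keys}")

    tracks = []
    for row in df.itertuples(index=False):
        linear = np.array([_parse_ratio_cell(getattr(row, c)) for c in _T_COLS])
        with np.errstate(divide="ignore", invalid="ignore"):
            log2fc = np.where(linear > 0, np.log2(np.where(linear > 0, linear, 1.0)), np.nan)
        tracks.append(ProteinAbundanceTrack(
            protein=row.protein, stimulus=row.stimulus, log2fc_series=log2fc))
    return tracks


def matrix_to_frame(matrix: ProfileMatrix) -> pd.DataFrame:
    """Serialize a ProfileMatrix to the ``simple`` dialect frame."""
    rows = []
    for p in matrix:
        row: dict = {"site_id": str(p.site), "stimulus": p.stimulus}
        for t, v in zip(TIME_GRID, p.log2fc):
            row[f"t{int(t)}"] = v
        for t in TIME_GRID:
            idx = int(t) // 2
            row[f"p{int(t)}"] = (
                p.localization_probs[idx] if p.localization_probs is not None else np.nan
            )
        rows.append(row)
    columns = ["site_id", "stimulus", *_T_COLS, *_P_COLS]
    return pd.DataFrame(rows, columns=columns)


def write_results(tables: dict[str, pd.DataFrame], out_dir,
                  manifest: dict | None = None) -> dict[str, Path]:
    """Write named result tables as TSV plus a JSON run manifest.

    Floats are written with full precision (repr round-trip) so that the
    simple-dialect round trip is bit-exact on the log2 scale.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, table in tables.items():
        target = out_dir / f"{name}.tsv"
        table.to_csv(target, sep="\t", index=False, float_format="%.17g")
        written[name] = target
    if manifest is not None:
        target = out_dir / "manifest.json"
        with open(target, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        written["manifest"] = target
    return written
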