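"""Shape-based selection of candidate regulated profiles.

Regulation is defined by the *shape* of a kinetic profile, not its
amplitude: a profile is a candidate when an ordinary least-squares
polynomial in time explains it well (R^2 strictly above a threshold,
default 0.9), after requiring at least 10 of 15 quantified points.
Candidates on proteins whose nonphosphopeptide abundance drifts by more
than a factor of two (max |log2FC| > 1, threshold exposed) are excluded,
since protein-level change would confound site-level dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FitUndefinedError, ParameterError
from .types import KineticProfile, ProfileMatrix, ProteinAbundanceTrack

EXCLUSION_REASONS = ("none", "too_few_points", "low_r2", "zero_variance", "abundance_drift")


@dataclass
class PolyFit:
    """OLS polynomial fit of one kinetic profile (coefficients ascending)."""

    degree: int
    coefficients: np.ndarray
    r2: float  # NaN when undefined (zero-variance response)
    n_obs: int
    rsd: float = float("nan")

    def predict(self, t) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(t, dtype=float),
                                                self.coefficients)


@dataclass
class SelectionResult:
    """Per-(site, stimulus) selection decisions plus the fitted models."""

    table: pd.DataFrame  # site_id, stimulus, protein, n_obs, passed_quality,
                         # r2, candidate, exclusion_reason
    fits: dict[tuple[str, str], PolyFit]

    @property
    def candidates(self) -> pd.DataFrame:
        return self.table[self.table["candidate"]]


def quality_filter(profile: KineticProfile, min_obs: int = 10) -> bool:
    """True iff the profile is quantified in at least ``min_obs`` points."""
    return profile.n_quantified >= min_obs


def fit_polynomial(profile: KineticProfile, degree: int = 3) -> PolyFit:
    """OLS polynomial in actual minutes over quantified points only.

    R^2 = 1 - SS_res/SS_tot about the mean of the observed log2FC values;
    a constant profile (SS_tot = 0) yields NaN R^2 and is treated as not
    regulated downstream.
    """
    mask = ~profile.missing_mask
    t = profile.times[mask]
    y = profile.log2fc[mask]
    n_obs = len(y)
    if n_obs < degree + 2:
        raise FitUndefinedError(
            f"{profile.key}: {n_obs} points cannot support degree {degree} "
            f"(need >= {degree + 2})")
    coeffs = np.polynomial.polynomial.polyfit(t, y, deg=degree)
    residuals = y - np.polynomial.polynomial.polyval(t, coeffs)
    ss_res = float(np.sum(residuals ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    scale = max(1.0, float(np.max(np.abs(y))))
    if ss_tot <= n_obs * (1e-12 * scale) ** 2:  # constant up to rounding
        r2 = float("nan")
    else:
        r2 = 1.0 - ss_res / ss_tot
        r2 = min(max(r2, 0.0), 1.0)
    rsd = float(np.std(residuals, ddof=min(degree + 1, n_obs - 1)) / abs(y.mean())) \
        if y.mean() != 0 else float("nan")
    return PolyFit(degree=degree, coefficients=coeffs, r2=r2, n_obs=n_obs, rsd=rsd)


def select_candidates(matrix: ProfileMatrix, r2_threshold: float = 0.9,
                      degree: int = 3, min_obs: int = 10) -> SelectionResult:
    """Per-profile candidate decision with exclusion reasons.

    The quality gate is max(min_obs, degree + 5): with the default 10-point
    requirement and cubic model this is just the 10-point rule, but it
    protects against trivially perfect fits if the caller lowers min_obs.
    """
    if not 0.0 <= r2_threshold <= 1.0:
        raise ParameterError("r2_threshold must lie in [0, 1]")
    required = max(min_obs, degree + 5)
    rows = []
    fits: dict[tuple[str, str], PolyFit] = {}
    for profile in matrix:
        site_id, stimulus = profile.key
        n_obs = profile.n_quantified
        passed_quality = n_obs >= required
        r2 = float("nan")
        reason = "none"
        candidate = False
        if not passed_quality:
            reason = "too_few_points"
        else:
            fit = fit_polynomial(profile, degree=degree)
            fits[profile.key] = fit
            r2 = fit.r2
            if np.isnan(r2):
                reason = "zero_variance"
            elif r2 > r2_threshold:
                candidate = True
            else:
                reason = "low_r2"
        rows.append((site_id, stimulus, profile.site.protein, n_obs,
                     passed_quality, r2, candidate, reason))
    table = pd.DataFrame(rows, columns=["site_id", "stimulus", "protein", "n_obs",
                                        "passed_quality", "r2", "candidate",
                                        "exclusion_reason"])
    return SelectionResult(table=table, fits=fits)


def abundance_exclusion(selection: SelectionResult,
                        tracks: list[ProteinAbundanceTrack],
                        max_abs_log2fc: float = 1.0) -> SelectionResult:
    """Drop candidates on proteins whose abundance drifts beyond the cap.

    A protein drifts when any of its tracks exceeds ``max_abs_log2fc`` in
    absolute log2 fold change at any time point. Proteins without a track
    are retained (protein-level coverage is partial in practice).
    """
    drifting: set[str] = set()
    for track in tracks:
        m = track.max_abs_log2fc()
        if np.isfinite(m) and m > max_abs_log2fc:
            drifting.add(track.protein)
    table = selection.table.copy()
    hit = table["candidate"] & table["protein"].isin(drifting)
    table.loc[hit, "candidate"] = False
    table.loc[hit, "exclusion_reason"] = "abundance_drift"
    return SelectionResult(table=table, fits=selection.fits)
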