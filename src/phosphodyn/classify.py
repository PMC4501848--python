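"""Cross-stimulus classification of dynamic phosphosites.

Each site is dynamic for a stimulus when that stimulus-profile passed both
the polynomial-R^2 filter and the cluster-membership filter. Sites dynamic
under both stimuli are split by the sign of the dominant fitted excursion:
opposite signs = bidirectional, same sign = temperature-independent;
single-stimulus sites are heat- or cold-specific, the rest static. The
sign of the dominant excursion (rather than the endpoint fold change) is
used because adaptation-like profiles can end near baseline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataIntegrityError
from .selection import PolyFit, SelectionResult
from .types import TIME_GRID, PhosphoSiteID

CATEGORY_VALUES = ("bidirectional", "temperature_independent",
                   "heat_specific", "cold_specific", "static")

#: dense evaluation grid for locating the fitted curve's extremum
_FINE_GRID = np.linspace(TIME_GRID[0], TIME_GRID[-1], 113)


def profile_direction(fit: PolyFit, grid: np.ndarray | None = None) -> float:
    """Signed dominant excursion of the fitted curve, relative to t = 0.

    The fitted polynomial is evaluated on a dense grid; the return value
    is the curve value (minus the fitted value at time zero) of largest
    absolute magnitude — positive for a net phosphorylation increase,
    negative for a decrease, 0 for a flat fit.
    """
    if fit is None:
        raise DataIntegrityError("profile_direction requires a defined fit")
    g = _FINE_GRID if grid is None else np.asarray(grid, dtype=float)
    curve = fit.predict(g) - fit.predict(g[:1])[0]
    idx = int(np.argmax(np.abs(curve)))
    return float(curve[idx])


def _curve_correlation(fit_a: PolyFit | None, fit_b: PolyFit | None) -> float:
    if fit_a is None or fit_b is None:
        return float("nan")
    a = fit_a.predict(_FINE_GRID)
    b = fit_b.predict(_FINE_GRID)
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def classify_site(site_id: str,
                  heat: tuple[bool, PolyFit | None],
                  cold: tuple[bool, PolyFit | None]) -> dict:
    """Apply the four-category decision table to one site."""
    heat_dynamic, heat_fit = heat
    cold_dynamic, cold_fit = cold
    if heat_dynamic and heat_fit is None:
        raise DataIntegrityError(f"{site_id}: heat-dynamic without a defined fit")
    if cold_dynamic and cold_fit is None:
        raise DataIntegrityError(f"{site_id}: cold-dynamic without a defined fit")

    heat_dir = profile_direction(heat_fit) if heat_fit is not None else 0.0
    cold_dir = profile_direction(cold_fit) if cold_fit is not None else 0.0

    if heat_dynamic and cold_dynamic:
        category = ("bidirectional" if np.sign(heat_dir) != np.sign(cold_dir)
                    else "temperature_independent")
    elif heat_dynamic:
        category = "heat_specific"
    elif cold_dynamic:
        category = "cold_specific"
    else:
        category = "static"

    return {
        "site_id": site_id,
        "protein": PhosphoSiteID.parse(site_id).protein,
        "heat_dynamic": heat_dynamic,
        "cold_dynamic": cold_dynamic,
        "heat_direction": heat_dir,
        "cold_direction": cold_dir,
        "category": category,
        "direction_score": _curve_correlation(heat_fit, cold_fit),
    }


def classify_all(selection: SelectionResult, dynamic_profiles: pd.DataFrame) -> pd.DataFrame:
    """Classify every site appearing in the selection table.

    ``dynamic_profiles`` is the membership-filter output whose
    ``profile_id`` entries are ``(site_id, stimulus)`` tuples or
    "site_id|stimulus" strings identifying profiles in the dynamic set.
    """
    dynamic_keys = set()
    for pid in dynamic_profiles["profile_id"]:
        if isinstance(pid, str) and "|" in pid:
            site_id, stim = pid.rsplit("|", 1)
            dynamic_keys.add((site_id, stim))
        else:
            dynamic_keys.add(tuple(pid))

    rows = []
    for site_id in selection.table["site_id"].unique():
        heat_key = (site_id, "heat")
        cold_key = (site_id, "cold")
        rows.append(classify_site(
            site_id,
            heat=(heat_key in dynamic_keys, selection.fits.get(heat_key)),
            cold=(cold_key in dynamic_keys, selection.fits.get(cold_key)),
        ))
    return pd.DataFrame(rows)


def summarize_proteins(classifications: pd.DataFrame) -> pd.DataFrame:
    """Per-protein multiset of site categories.

    A protein is ``multi_category`` when its sites span two or more
    distinct non-static categories (e.g. one bidirectional and one
    heat-specific site on the same protein).
    """
    cols = ["protein", "n_dynamic_sites", "categories", "multi_category"]
    if classifications.empty:
        return pd.DataFrame(columns=cols)
    dynamic = classifications[classifications["category"] != "static"]
    rows = []
    for protein, group in dynamic.groupby("protein", sort=True):
        cats = sorted(set(group["category"]))
        rows.append((protein, len(group), ",".join(cats), len(cats) >= 2))
    return pd.DataFrame(rows, columns=cols)
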