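"""Kinase-centric analyses: group distributions and substrate inference.

Substrate inference combines three evidence channels: (i) a scored
protein-interaction edge between the kinase and the site's protein at
high confidence (score >= 0.9 by default), (ii) prior annotation of the
site as a known target of the kinase, and (iii) kinetic-profile
similarity — the Pearson correlation between the site's time course and
the kinase's reference profile. Correlated mode suits activating kinase
phosphosites; anticorrelated mode encodes inhibitory-site logic (kinase
inhibitory phosphorylation up implies substrate dephosphorylation). The
mode is a per-kinase user choice, not inferred.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ParameterError
from .types import PhosphoSiteID, ProfileMatrix


def profile_similarity(a, b) -> float:
    """Pearson correlation over time points quantified in both profiles.

    Returns NaN when fewer than three shared points exist or either
    profile has zero variance over them.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ParameterError("profiles must share a time grid")
    mask = np.isfinite(a) & np.isfinite(b)
    if mask.sum() < 3:
        return float("nan")
    x, y = a[mask], b[mask]
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def kinase_group_distribution(classifications: pd.DataFrame,
                              predictions: pd.DataFrame) -> pd.DataFrame:
    """Counts and proportions of predicted kinase groups, dynamic vs static.

    A site predicted for several groups contributes one count to each
    group. Proportions are within the dynamic and static columns.
    """
    cols = ["kinase_group", "dynamic", "static", "prop_dynamic", "prop_static"]
    if predictions.empty or classifications.empty:
        return pd.DataFrame(columns=cols)
    status = classifications.set_index("site_id")["category"].map(
        lambda c: "static" if c == "static" else "dynamic")
    pred = predictions.drop_duplicates(subset=["site_id", "kinase_group"]).copy()
    pred["status"] = pred["site_id"].map(status)
    pred = pred.dropna(subset=["status"])
    counts = (pred.groupby(["kinase_group", "status"]).size()
              .unstack(fill_value=0).reindex(columns=["dynamic", "static"], fill_value=0))
    out = counts.reset_index()
    for col in ("dynamic", "static"):
        total = out[col].sum()
        out[f"prop_{col}"] = out[col] / total if total else 0.0
    return out[cols]


def cluster_kinase_composition(dynamic_sites: pd.DataFrame,
                               predictions: pd.DataFrame) -> pd.DataFrame:
    """Kinase-group x cluster count matrix over the dynamic set.

    ``dynamic_sites`` needs columns ``site_id`` and ``cluster``; marginals
    equal the input counts by construction.
    """
    if dynamic_sites.empty or predictions.empty:
        return pd.DataFrame()
    pred = predictions.drop_duplicates(subset=["site_id", "kinase_group"])
    merged = dynamic_sites.merge(pred[["site_id", "kinase_group"]], on="site_id")
    return (merged.groupby(["kinase_group", "cluster"]).size()
            .unstack(fill_value=0))


def candidate_substrates(kinase: str,
                         reference_profile,
                         edges: pd.DataFrame,
                         known_sites: pd.DataFrame,
                         dynamic_profiles: pd.DataFrame,
                         matrix: ProfileMatrix,
                         kinase_protein: str | None = None,
                         stimulus: str = "heat",
                         min_edge_score: float = 0.9,
                         min_abs_similarity: float = 0.7,
                         mode: str = "correlated") -> pd.DataFrame:
    """Rank dynamic sites on high-confidence kinase interactors by profile similarity.

    Parameters
    ----------
    reference_profile : array-like
        The kinase's own dynamic-site time course (or a designated cluster
        centroid) on the standard grid; NaN marks missing points.
    edges : DataFrame
        Undirected scored interactions: protein_a, protein_b, combined_score.
    known_sites : DataFrame
        Prior kinase-target annotation: kinase, protein, position, residue.
    dynamic_profiles : DataFrame
        The membership-filter output ("site_id|stimulus" profile ids with
        cluster labels).
    matrix : ProfileMatrix
        Source of the site time courses.
    mode : {"correlated", "anticorrelated"}
        Which sign of similarity counts as supporting evidence.
    """
    if mode not in ("correlated", "anticorrelated"):
        raise ParameterError(f"unknown mode: {mode!r}")
    reference = np.asarray(reference_profile, dtype=float)
    if not np.any(np.isfinite(reference)):
        raise ParameterError("reference profile is entirely missing")
    kinase_protein = kinase_protein or kinase

    # proteins connected to the kinase at high confidence
    e = edges[pd.to_numeric(edges["combined_score"]) >= min_edge_score]
    partners = set(e.loc[e["protein_a"] == kinase_protein, "protein_b"])
    partners |= set(e.loc[e["protein_b"] == kinase_protein, "protein_a"])

    known = set()
    if known_sites is not None and len(known_sites):
        k = known_sites[known_sites["kinase"] == kinase]
        known = {(str(r.protein), int(r.position)) for r in k.itertuples()}

    rows = []
    for pid_raw in dynamic_profiles["profile_id"]:
        pid = pid_raw if isinstance(pid_raw, str) else "|".join(pid_raw)
        site_id, stim = pid.rsplit("|", 1)
        if stim != stimulus:
            continue
        site = PhosphoSiteID.parse(site_id)
        if site.protein not in partners:
            continue
        profile = matrix.get(site_id, stim)
        if profile is None:
            continue
        sim = profile_similarity(reference, profile.log2fc)
        if np.isnan(sim):
            continue
        signed_ok = sim >= min_abs_similarity if mode == "correlated" \
            else sim <= -min_abs_similarity
        if not signed_ok:
            continue
        rows.append({
            "kinase": kinase,
            "site_id": site_id,
            "protein": site.protein,
            "position": site.position,
            "similarity": sim,
            "mode": mode,
            "evidence_ppi": True,
            "evidence_known_site": (site.protein, site.position) in known,
        })
    out = pd.DataFrame(rows, columns=["kinase", "site_id", "protein", "position",
                                      "similarity", "mode", "evidence_ppi",
                                      "evidence_known_site"])
    if len(out):
        out["abs_similarity"] = out["similarity"].abs()
        out = (out.sort_values(["abs_similarity", "protein", "position"],
                               ascending=[False, True, True], kind="mergesort")
               .drop(columns="abs_similarity").reset_index(drop=True))
        out["rank"] = np.arange(1, len(out) + 1)
    else:
        out["rank"] = pd.Series(dtype=int)
    return out


def rank_interactors_by_similarity(kinase: str, reference_profile,
                                   edges: pd.DataFrame,
                                   matrix: ProfileMatrix,
                                   kinase_protein: str | None = None,
                                   stimulus: str = "heat",
                                   min_edge_score: float = 0.0) -> pd.DataFrame:
    """Similarity score for every interactor site profile, no cutoff.

    Convenience view for ROC-style evaluation of the ranking itself: all
    edges above ``min_edge_score`` are scored, none filtered by
    similarity.
    """
    reference = np.asarray(reference_profile, dtype=float)
    kinase_protein = kinase_protein or kinase
    e = edges[pd.to_numeric(edges["combined_score"]) >= min_edge_score]
    partners = set(e.loc[e["protein_a"] == kinase_protein, "protein_b"])
    partners |= set(e.loc[e["protein_b"] == kinase_protein, "protein_a"])
    rows = []
    for profile in matrix:
        if profile.stimulus != stimulus or profile.site.protein not in partners:
            continue
        sim = profile_similarity(reference, profile.log2fc)
        rows.append((kinase, str(profile.site), profile.site.protein, sim))
    return pd.DataFrame(rows, columns=["kinase", "site_id", "protein", "similarity"])
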