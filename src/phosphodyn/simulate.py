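"""Synthetic SILAC phosphosite time courses with planted structure.

The generator emulates the study design the pipeline targets: two stimuli
(heat shock, cold stress) per phosphosite, 15 time points at 2-min spacing
over 0-28 min, log2 fold-change profiles with either saturating
("monotone") or transient ("adaptation") shapes, multiplicative lognormal
measurement noise with a stated coefficient of variation, independent
per-point missingness, a planted four-category heat/cold response
structure, and planted kinase-substrate co-dynamics (substrate profiles
share their kinase's template) with a scored protein-interaction network
around them.

Every draw flows from a single :class:`numpy.random.Generator` seeded from
``SimulationConfig.seed``, so one seed reproduces the dataset bit-exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .types import (
    TIME_GRID,
    KineticProfile,
    PhosphoSiteID,
    ProfileMatrix,
    ProteinAbundanceTrack,
)

CATEGORIES = ("bidirectional", "temperature_independent", "heat_specific", "cold_specific")

# Observed per-category shares of dynamic sites (~25% opposite-trend,
# ~11% same-trend, ~46% heat-only, ~1% cold-only), normalized to a proper
# distribution over the four dynamic categories.
_RAW_MIX = np.array([0.25, 0.11, 0.46, 0.01])
DEFAULT_CATEGORY_MIX = tuple(_RAW_MIX / _RAW_MIX.sum())


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Defaults mirror the experimental setting the pipeline analyzes:
    measurement CV 0.29, ~14% of sites dynamic, heat responses on average
    twice the amplitude of cold responses, and a majority of
    adaptation-like (transient) shapes among dynamic profiles.
    """

    n_sites: int = 1000
    frac_dynamic: float = 0.14
    category_mix: tuple[float, float, float, float] = DEFAULT_CATEGORY_MIX
    template_mix: tuple[float, float] = (0.4, 0.6)  # (monotone, adaptation)
    amplitude_range: tuple[float, float] = (1.0, 4.0)  # |log2FC| at the extremum (heat)
    heat_cold_amplitude_ratio: float = 1.0
    cv_noise: float = 0.29
    missing_rate: float = 0.08
    frac_unlocalized: float = 0.05  # sites given low localization confidence
    n_kinases: int = 3
    substrates_per_kinase: int = 5
    n_decoy_edges_per_kinase: int = 20
    frac_high_score_decoys: float = 0.25
    known_site_fraction: float = 0.5
    substrate_timescale_jitter: float = 0.15
    substrate_amplitude_jitter: float = 0.15
    frac_drifting_proteins: float = 0.01
    drift_log2fc: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ParameterError("n_sites must be >= 1")
        if not 0.0 <= self.frac_dynamic <= 1.0:
            raise ParameterError("frac_dynamic must lie in [0, 1]")
        for name in ("category_mix", "template_mix"):
            mix = np.asarray(getattr(self, name), dtype=float)
            if np.any(mix < 0) or np.any(mix > 1):
                raise ParameterError(f"{name} fractions must lie in [0, 1]")
            if abs(mix.sum() - 1.0) > 1e-9:
                raise ParameterError(f"{name} must sum to 1, got {mix.sum()!r}")
        if self.amplitude_range[0] <= 0 or self.amplitude_range[1] < self.amplitude_range[0]:
            raise ParameterError("amplitude_range must be positive and ordered")
        if self.cv_noise < 0:
            raise ParameterError("cv_noise must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ParameterError("missing_rate must lie in [0, 1)")


@dataclass
class GroundTruth:
    """Planted per-site truth, the oracle for every downstream stage."""

    sites: pd.DataFrame  # site_id, protein, category, template, amp_heat, amp_cold,
                         # timescale, kinase
    kinase_substrates: dict[str, list[str]] = field(default_factory=dict)
    kinase_proteins: dict[str, str] = field(default_factory=dict)

    @property
    def dynamic_site_ids(self) -> list[str]:
        mask = self.sites["category"] != "static"
        return list(self.sites.loc[mask, "site_id"])


def make_template(kind: str, amplitude: float, timescale: float,
                  grid: np.ndarray = TIME_GRID) -> np.ndarray:
    """Noiseless log2FC response curve, anchored at 0 at t=0.

    ``monotone``: amplitude * (1 - 2**(-t/timescale)) — saturating; with
    timescale ~5 min the curve plateaus by ~20 min.
    ``adaptation``: amplitude * (t/timescale) * exp(1 - t/timescale) — a
    unit-peak gamma pulse peaking at t = timescale and relaxing toward 0.
    """
    if timescale <= 0:
        raise ParameterError("timescale must be > 0")
    t = np.asarray(grid, dtype=float)
    if kind == "monotone":
        return amplitude * (1.0 - 2.0 ** (-t / timescale))
    if kind == "adaptation":
        return amplitude * (t / timescale) * np.exp(1.0 - t / timescale)
    raise ParameterError(f"unknown template kind: {kind!r}")


def _lognormal_log2_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """log2 of a unit-mean lognormal factor with the given linear-scale CV."""
    if cv == 0:
        return np.zeros(size)
    sigma2 = math.log1p(cv * cv)
    sigma = math.sqrt(sigma2)
    # mean of the linear factor is 1 => mu = -sigma^2/2
    normal = rng.normal(loc=-sigma2 / 2.0, scale=sigma, size=size)
    return normal / math.log(2.0)


def simulate_dataset(config: SimulationConfig) -> tuple[ProfileMatrix,
                                                        list[ProteinAbundanceTrack],
                                                        GroundTruth]:
    """Draw a full two-stimulus dataset plus its ground truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_sites
    n_dynamic = int(round(n * config.frac_dynamic))

    # --- plant per-site truth -------------------------------------------
    categories = np.array(["static"] * n, dtype=object)
    if n_dynamic:
        dyn_idx = rng.choice(n, size=n_dynamic, replace=False)
        cats = rng.choice(len(CATEGORIES), size=n_dynamic, p=np.asarray(config.category_mix))
        categories[dyn_idx] = np.array(CATEGORIES, dtype=object)[cats]

    templates = np.where(rng.random(n) < config.template_mix[0], "monotone", "adaptation")
    lo, hi = config.amplitude_range
    amp_heat = rng.uniform(lo, hi, size=n) * rng.choice([-1.0, 1.0], size=n)
    amp_cold_mag = np.abs(amp_heat) / config.heat_cold_amplitude_ratio
    # monotone: plateau by ~20 min; adaptation: peak mid-window, relaxing
    # toward baseline by 28 min (transients peaking earlier than ~6 min are
    # not representable by the default cubic shape filter and would leave
    # the planted truth unrecoverable by design)
    timescales = np.where(templates == "monotone",
                          rng.uniform(3.0, 6.0, size=n),
                          rng.uniform(6.5, 10.0, size=n))

    heat_amp = np.zeros(n)
    cold_amp = np.zeros(n)
    for i, cat in enumerate(categories):
        if cat == "bidirectional":
            heat_amp[i] = amp_heat[i]
            cold_amp[i] = -np.sign(amp_heat[i]) * amp_cold_mag[i]
        elif cat == "temperature_independent":
            heat_amp[i] = amp_heat[i]
            cold_amp[i] = np.sign(amp_heat[i]) * amp_cold_mag[i]
        elif cat == "heat_specific":
            heat_amp[i] = amp_heat[i]
        elif cat == "cold_specific":
            cold_amp[i] = np.sign(amp_heat[i]) * amp_cold_mag[i]

    # --- kinase assignments ---------------------------------------------
    kinase_of = np.array([""] * n, dtype=object)
    kinase_substrates: dict[str, list[str]] = {}
    kinase_proteins: dict[str, str] = {}
    dynamic_indices = [i for i in range(n) if categories[i] != "static"]
    needed = config.n_kinases * (1 + config.substrates_per_kinase)
    if config.n_kinases and len(dynamic_indices) >= needed:
        picked = rng.choice(dynamic_indices, size=needed, replace=False)
        cursor = 0
        for kk in range(config.n_kinases):
            k_idx = int(picked[cursor]); cursor += 1
            kname = f"KIN{kk + 1}"
            kinase_of[k_idx] = kname + ":self"
            kinase_proteins[kname] = f"P{k_idx + 1:05d}"
            members = []
            for _ in range(config.substrates_per_kinase):
                s_idx = int(picked[cursor]); cursor += 1
                kinase_of[s_idx] = kname
                # substrates inherit the kinase's template shape with jitter
                templates[s_idx] = templates[k_idx]
                ts_jit = 1.0 + config.substrate_timescale_jitter * rng.standard_normal()
                timescales[s_idx] = timescales[k_idx] * max(ts_jit, 0.2)
                amp_jit = 1.0 + config.substrate_amplitude_jitter * rng.standard_normal()
                scale = abs(amp_jit)
                # align the substrate's heat response with the kinase's, then
                # re-derive cold from the substrate's own category so the
                # planted four-category structure stays intact
                ref_sign = np.sign(heat_amp[k_idx]) or np.sign(cold_amp[k_idx]) or 1.0
                cat = categories[s_idx]
                if cat == "bidirectional":
                    heat_amp[s_idx] = ref_sign * abs(heat_amp[s_idx]) * scale
                    cold_amp[s_idx] = -ref_sign * abs(cold_amp[s_idx]) * scale
                elif cat == "temperature_independent":
                    heat_amp[s_idx] = ref_sign * abs(heat_amp[s_idx]) * scale
                    cold_amp[s_idx] = ref_sign * abs(cold_amp[s_idx]) * scale
                elif cat == "heat_specific":
                    heat_amp[s_idx] = ref_sign * abs(heat_amp[s_idx]) * scale
                elif cat == "cold_specific":
                    cold_amp[s_idx] = ref_sign * abs(cold_amp[s_idx]) * scale
                members.append(s_idx)
            kinase_substrates[kname] = members  # indices for now

    # --- materialize profiles -------------------------------------------
    residues = rng.choice(["S", "T", "Y"], size=n, p=[0.75, 0.2, 0.05])
    site_ids = []
    profiles = []
    unlocalized = rng.random(n) < config.frac_unlocalized
    for i in range(n):
        site = PhosphoSiteID(protein=f"P{i + 1:05d}", position=int(rng.integers(1, 800)),
                             residue=str(residues[i]), multiplicity=1)
        site_ids.append(str(site))
        for stim, amp in (("heat", heat_amp[i]), ("cold", cold_amp[i])):
            curve = (make_template(str(templates[i]), amp, float(timescales[i]))
                     if amp != 0 else np.zeros(len(TIME_GRID)))
            noisy = curve + _lognormal_log2_noise(rng, config.cv_noise, len(TIME_GRID))
            missing = rng.random(len(TIME_GRID)) < config.missing_rate
            noisy = np.where(missing, np.nan, noisy)
            if unlocalized[i]:
                probs = rng.uniform(0.2, 0.6, size=len(TIME_GRID))
            else:
                probs = rng.uniform(0.85, 1.0, size=len(TIME_GRID))
            probs = np.where(missing, np.nan, probs)
            profiles.append(KineticProfile(site=site, stimulus=stim,
                                           log2fc=noisy, localization_probs=probs))

    matrix = ProfileMatrix(profiles)

    # --- protein abundance tracks (nonphospho peptides) ------------------
    tracks = []
    drifting = rng.random(n) < config.frac_drifting_proteins
    for i in range(n):
        protein = f"P{i + 1:05d}"
        for stim in ("heat", "cold"):
            if drifting[i] and stim == "heat":
                base = make_template("monotone", config.drift_log2fc, 5.0)
            else:
                base = np.zeros(len(TIME_GRID))
            noisy = base + _lognormal_log2_noise(rng, config.cv_noise / 3.0, len(TIME_GRID))
            tracks.append(ProteinAbundanceTrack(protein=protein, stimulus=stim,
                                                log2fc_series=noisy))

    truth_sites = pd.DataFrame({
        "site_id": site_ids,
        "protein": [f"P{i + 1:05d}" for i in range(n)],
        "category": categories,
        "template": templates,
        "amp_heat": heat_amp,
        "amp_cold": cold_amp,
        "timescale": timescales,
        "kinase": kinase_of,
        "drifting_protein": drifting,
        "unlocalized": unlocalized,
    })
    truth = GroundTruth(
        sites=truth_sites,
        kinase_substrates={k: [site_ids[i] for i in v] for k, v in kinase_substrates.items()},
        kinase_proteins=kinase_proteins,
    )
    return matrix, tracks, truth


def simulate_kinase_network(config: SimulationConfig, truth: GroundTruth
                            ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Emit the kinase-prediction, PPI-edge and known-site tables.

    Each planted kinase gets high-confidence edges (score >= 0.9) to its
    substrate proteins, plus decoy edges to random non-substrate proteins
    (a configurable share of which also score >= 0.9, the hard decoys).
    Prediction rows assign each site's planted kinase (group = the kinase
    name's family, here one group per kinase); known-site rows cover a
    random subset of true substrates.
    """
    if not truth.kinase_substrates:
        raise ParameterError("ground truth contains no kinase assignments")
    rng = np.random.default_rng(config.seed + 1_000_003)
    sites = truth.sites.set_index("site_id")

    pred_rows, edge_rows, known_rows = [], [], []
    substrate_proteins = {p for members in truth.kinase_substrates.values()
                          for p in sites.loc[members, "protein"]}
    all_proteins = list(sites["protein"].unique())

    for kname, members in truth.kinase_substrates.items():
        kprot = truth.kinase_proteins[kname]
        group = f"{kname}_GROUP"
        for site_id in members:
            prot = sites.loc[site_id, "protein"]
            edge_rows.append((kprot, prot, float(rng.uniform(0.9, 0.999))))
            pred_rows.append((site_id, kname, group, float(rng.uniform(0.5, 1.0))))
            if rng.random() < config.known_site_fraction:
                sid = PhosphoSiteID.parse(site_id)
                known_rows.append((kname, sid.protein, sid.position, sid.residue))
        decoy_pool = [p for p in all_proteins
                      if p not in substrate_proteins and p != kprot]
        n_decoys = min(config.n_decoy_edges_per_kinase, len(decoy_pool))
        if n_decoys:
            decoys = rng.choice(decoy_pool, size=n_decoys, replace=False)
            for d in decoys:
                if rng.random() < config.frac_high_score_decoys:
                    score = float(rng.uniform(0.9, 0.999))
                else:
                    score = float(rng.uniform(0.15, 0.899))
                edge_rows.append((kprot, d, score))

    predictions = pd.DataFrame(pred_rows, columns=["site_id", "kinase", "kinase_group", "score"])
    edges = pd.DataFrame(edge_rows, columns=["protein_a", "protein_b", "combined_score"])
    known = pd.DataFrame(known_rows, columns=["kinase", "protein", "position", "residue"])
    return predictions, edges, known


def random_group_predictions(truth: GroundTruth, seed: int,
                             groups: tuple[str, ...] = ("CDK", "MAPK", "AGC", "CK1_2", "PAK"),
                             dynamic_bias: dict[str, float] | None = None) -> pd.DataFrame:
    """Assign kinase-group predictions to every site, optionally biased.

    ``dynamic_bias`` maps group name -> multiplicative weight applied for
    dynamic sites, emulating enrichment of e.g. CDK/MAPK substrates among
    dynamic phosphosites.
    """
    rng = np.random.default_rng(seed)
    base = np.ones(len(groups))
    rows = []
    for row in truth.sites.itertuples(index=False):
        weights = base.copy()
        if dynamic_bias and row.category != "static":
            for g, w in dynamic_bias.items():
                weights[groups.index(g)] *= w
        weights = weights / weights.sum()
        g = groups[int(rng.choice(len(groups), p=weights))]
        rows.append((row.site_id, f"{g}_member", g, float(rng.uniform(0.3, 1.0))))
    return pd.DataFrame(rows, columns=["site_id", "kinase", "kinase_group", "score"])
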