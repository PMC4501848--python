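# Methods

`phosphodyn` analyzes SILAC phosphoproteome time courses from temperature-shift
experiments in budding yeast: for every phosphosite, the log2 ratio of
phosphopeptide abundance between a stimulus culture (heat shock at 42 °C or
cold stress at 18 °C) and a 30 °C control, measured at 15 time points on a
2-minute grid from 0 to 28 minutes. This note describes the model behind each
stage, the parameters that matter, what the synthetic-data generator does and
does not emulate, and the numerical choices made where the design was open.

## Data model

A profile is one phosphosite × one stimulus: a 15-point log2 fold-change
series with an explicit missing mask (unquantified time points are NaN and are
never imputed at the I/O layer). Site identity is protein accession, 1-based
residue position, residue (S/T/Y) and phosphogroup multiplicity; peptide forms
of different multiplicity are distinct records because mono- and
di-phosphorylated forms of the same residue can behave differently. All
ratios are converted to the log2 scale on ingest; the `simple` TSV dialect
stores log2 values and round-trips losslessly, the MaxQuant-style dialect
stores linear ratios.

## Quality and localization filters

* **Quantification**: a profile must be quantified in ≥ 10 of 15 time points
  (`min_obs`, default 10).
* **Localization**: the mean phosphosite localization probability over
  quantified points must be ≥ 0.75 (`min_mean_prob`); profiles with no
  probabilities at all are dropped unless `keep_unscored` is set. The mean is
  taken over quantified points only — the average over all 15 points would
  penalize sites for missingness twice.

## Global variability (IQR)

The proteome-wide effect of a stimulus at time t is the interquartile range of
the log2 FC distribution over all quantified profiles at t. Quantiles use
linear interpolation (the p-quantile of sorted x₁..xₙ interpolates at rank
1+(n−1)p); the convention is recorded in the run manifest because IQR values
shift by a few percent between quantile definitions at moderate n. The
nonphosphopeptide (protein-level) IQR serves as the technical baseline; the
technical coefficient of variation is sample sd / mean of linear ratios.

## Dynamic-profile selection

Regulation is assigned by profile *shape*, not amplitude: an ordinary
least-squares polynomial in actual minutes (degree 3 by default) is fitted to
the quantified points, and a profile is a candidate when R² > 0.9 (strict).
R² is 1 − SS_res/SS_tot about the observed mean; constant profiles
(SS_tot = 0 up to rounding) are flagged `zero_variance` and treated as not
regulated. Degree 3 is the lowest degree able to represent single-peaked
adaptation-like responses; it is configurable, and a guard requires
n_obs ≥ degree + 5 so that small-n fits cannot be trivially perfect. Missing
points are omitted from the fit, not imputed. No separate residual-RSD cutoff
is applied: noisy profiles fail the R² criterion directly.

Candidates on proteins whose nonphosphopeptide abundance track exceeds
|log2FC| = 1 (i.e. a two-fold protein-level change) at any time point are
excluded as `abundance_drift`; proteins without a track are retained, since
protein-level coverage is partial in practice.

### Operating characteristics

With independent multiplicative noise at CV 0.29 per point, the cubic-R²
criterion is stringent: pure-noise (static) profiles pass at well under 5%,
but a dynamic profile needs a large amplitude (roughly |log2FC| ≳ 3 at the
extremum for saturating shapes) for its expected R² to clear 0.9. The test
suite therefore asserts ≥ 95% sensitivity on *noiseless* planted dynamics and
< 5% false selection at CV 0.29; under the full noise model the pipeline
recovers the strongest planted responses, which is the intended behavior of a
shape filter this strict.

## Fuzzy c-means clustering

Candidate profiles from both stimuli are clustered jointly (the analysis
compares shapes across stimuli, and per-cluster stimulus composition is a
readout, not an input). Each profile is completed — interior gaps by linear
interpolation in time, edge gaps by nearest observed value — and standardized
to mean 0, sd 1, so that clustering groups shapes rather than amplitudes;
low-amplitude profiles are deliberately on an equal footing.

Fuzzy c-means minimizes J = Σᵢⱼ uᵢⱼᵐ ‖xᵢ − cⱼ‖² by alternating the membership
update uᵢⱼ = 1/Σₗ (dᵢⱼ/dᵢₗ)^(2/(m−1)) and the weighted-centroid update.
Memberships are computed as a softmax over −log d²/(m−1), which is
algebraically identical but numerically stable as m → 1⁺ (where the partition
hardens to k-means). A vector coincident with a centroid receives membership
1 there. Initialization draws membership rows from a flat Dirichlet; the best
of `restarts` (default 20) seeded restarts by final objective is kept, and
seed plus restart count go into the manifest.

* **Fuzzifier m** is set analytically from the data dimensions:
  m = 1 + (1418/N + 22.05)·D⁻² + (12.33/N + 0.243)·D^(−0.0406 ln N − 0.1134),
  with N profiles in D = 15 dimensions; m decreases toward 1 as N and D grow.
  On a few hundred candidate profiles this lands near 1.25–1.30.
* **Cluster number k** is chosen by scanning k = 6..30 and recording the
  minimum centroid distance MCD(k), the smallest pairwise Euclidean distance
  between centroids. The elbow is the interior k with the most negative
  discrete second difference MCD(k−1) − 2·MCD(k) + MCD(k+1) — the last k whose
  centroids are still well separated before one more cluster collapses the
  minimum distance. (The opposite sign would select the bottom of the cliff,
  one past the true structure; on planted four-template data only the
  concavity rule recovers k = 4.) A manual override is available and is
  recorded in the manifest.
* **Dynamic set**: profiles whose maximum membership strictly exceeds 0.7 are
  "dynamic", labeled with their argmax cluster.

## Response classification

A site is dynamic *for a stimulus* iff that stimulus-profile independently
passed the R² and membership filters. The four-category decision table:

| heat dynamic | cold dynamic | sign(heat) vs sign(cold) | category |
|---|---|---|---|
| yes | yes | opposite | bidirectional |
| yes | yes | same | temperature_independent |
| yes | no | — | heat_specific |
| no | yes | — | cold_specific |
| no | no | — | static |

"Sign" is the sign of the dominant fitted excursion: the fitted curve is
evaluated densely over 0–28 min, referenced to its value at t = 0, and the
value of largest magnitude gives the signed amplitude. This is robust for
adaptation-like profiles, which can end near baseline where an endpoint rule
would misread them. The Pearson correlation of the two fitted curves is
reported as a diagnostic (`direction_score`) but does not enter the decision.
A protein is `multi_category` when its dynamic sites span ≥ 2 distinct
non-static categories.

## Kinase–substrate inference

Predicted kinase-group tables (NetworKIN/KinomeXplorer-style exports), scored
PPI edge lists (STRING-style) and known kinase-target annotations
(PhosphoGRID-style) are consumed as files, never computed. Candidate
substrates for a kinase are dynamic sites on proteins connected to the kinase
at edge score ≥ 0.9 whose profile correlates with the kinase's reference
profile at |r| ≥ 0.7 (Pearson over shared quantified points, ≥ 3 required).
The correlation *mode* is a required per-kinase input: `correlated` for
activating kinase phosphosites, `anticorrelated` for inhibitory-site logic
(kinase inhibitory phosphorylation up ⇒ substrate dephosphorylation).
Candidates are ranked by |r| with deterministic ties broken by
(protein, position). The 0.7 similarity cutoff is a conservative default,
symmetric with the membership threshold; network-wide summaries use edge
score ≥ 0.7, substrate inference ≥ 0.9 — both exposed as flags.

## Synthetic-data generator

The generator plants the structures every downstream stage must recover, and
its defaults are the study conditions used throughout the tests:

| parameter | default | meaning |
|---|---|---|
| n_sites | 1000 | phosphosites (two profiles each) |
| frac_dynamic | 0.14 | share of sites with a planted response |
| category_mix | 0.301/0.133/0.554/0.012 | bidirectional / temp-independent / heat-specific / cold-specific |
| template_mix | 0.4/0.6 | monotone vs adaptation shapes |
| amplitude_range | (1.0, 4.0) | \|log2FC\| at the extremum |
| cv_noise | 0.29 | CV of multiplicative measurement noise |
| missing_rate | 0.08 | independent per-point dropout |
| n_kinases / substrates_per_kinase | 3 / 5 | planted co-dynamic groups |

Shapes: `monotone` is A·(1 − 2^(−t/τ)) (plateau by ~20 min for τ ≈ 5);
`adaptation` is the unit-peak gamma pulse A·(t/τ)·e^(1−t/τ), peaking at
t = τ and relaxing toward baseline. Adaptation timescales are drawn from
6.5–10 min: a transient peaking much before 6 min is not representable by
the default cubic shape filter, so planting one would make the truth
unrecoverable by construction (this also means very early transients — of
which real data contain some — are a known blind spot of the default
degree-3 filter). Monotone timescales are 3–6 min.

Noise is multiplicative lognormal on the linear ratio scale with unit mean
and σ² = ln(1 + CV²) — SILAC ratio noise is relative — applied as an additive
log2 perturbation. Missingness is independent per point (no
intensity-dependent mechanism). Cold amplitudes are drawn on the same scale
as heat by default; a `heat_cold_amplitude_ratio` knob scales them down for
experiments contrasting stimulus strength. A small fraction (1%) of proteins
receive drifting abundance tracks (log2FC reaching 2.0) to exercise the
exclusion filter, and 5% of sites get low localization probabilities to
exercise the localization filter.

Planted kinase groups: each kinase is itself a dynamic site; its substrates
inherit the kinase's template with configurable timescale/amplitude jitter
(15%), and the emitted network contains true edges (score ≥ 0.9) plus decoy
edges to non-substrate proteins (20 per kinase, 25% of them in the
high-confidence band).

**What the generator does not emulate**: peptide detectability and
intensity-dependent missingness, SILAC channel cross-talk or arginine
conversion, correlated noise across neighboring time points, multi-site
peptides sharing measurements, and promiscuous low-stoichiometry
phosphorylation. Passing tests therefore demonstrate algorithmic correctness
and recovery of cleanly planted structure, not robustness to every artifact
of real MS data.

## Determinism and problem sizes

Every stochastic stage (generator, clustering restarts) flows from explicit
integer seeds recorded in the run manifest; two runs with the same seeds are
bit-identical, file for file. The bundled analysis scripts use 5,000 sites
(10,000 profiles) for the end-to-end narrative and the test suite uses
500–2,000 sites per property; these sizes give stable Monte-Carlo estimates
(binomial standard errors below the asserted margins) while keeping a full
run in seconds.

## Known limitations

* Category recovery through the *full* pipeline is limited by one-sided
  detection: when only one stimulus-profile of a genuinely both-responsive
  site clears R² > 0.9, the site is classified as stimulus-specific. The
  classification stage itself, given correct dynamic flags, recovers planted
  categories at ≥ 90% (asserted in the tests); end-to-end agreement is lower
  and is reported, not asserted.
* The MCD elbow is a heuristic; on weakly structured candidate sets the
  selected k varies with seed and restart count, which is why the manual
  override exists and is manifest-recorded.
* Profile correlation cannot distinguish a kinase's substrates from
  co-regulated non-substrates that share its temporal program; the PPI and
  known-site evidence channels exist precisely to narrow that ambiguity.
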