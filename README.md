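# phosphodyn

Analysis of high temporal resolution phosphoproteome dynamics under
temperature stress. Starting from per-phosphosite SILAC ratio time courses —
log2(stimulus/control) measured every 2 minutes for 28 minutes under two
stimuli (heat shock and cold stress) — the package selects regulated
phosphosites by the *shape* of their kinetic profiles, soft-clusters them,
classifies each site's cross-stimulus behavior, and infers candidate kinase
substrates from shared kinetics over a protein-interaction network. A
synthetic-data generator plants all of this structure so every stage is
testable without any mass-spectrometry download.

It is written for computational proteomics researchers who want a tested,
reproducible implementation of this kind of time-course pipeline, either to
run on MaxQuant-style site tables or to study the method's operating
characteristics on simulated data.

## The method

1. **Quality filters** — keep profiles quantified in ≥ 10 of 15 time points
   with mean site-localization probability ≥ 0.75.
2. **Global variability** — per-time-point interquartile range (IQR) of the
   log2 FC distribution, against the nonphosphopeptide technical baseline
   (CV = sd/mean of linear ratios).
3. **Shape selection** — ordinary least-squares cubic in time per profile;
   candidates have R² > 0.9 (strict). Candidates on proteins whose abundance
   drifts more than two-fold are excluded.
4. **Fuzzy c-means** — standardized, gap-imputed profiles (both stimuli
   jointly); fuzzifier m = 1 + (1418/N + 22.05)·D⁻² +
   (12.33/N + 0.243)·D^(−0.0406 ln N − 0.1134); cluster number chosen by the
   elbow of the minimum-centroid-distance curve over k = 6..30; profiles with
   maximum membership > 0.7 form the **dynamic** set.
5. **Classification** — per site: bidirectional (opposite fitted excursions
   under heat vs cold), temperature-independent (same direction),
   heat-/cold-specific, or static.
6. **Kinase–substrate inference** — dynamic sites on high-confidence
   interactors (PPI score ≥ 0.9) of a kinase, ranked by Pearson correlation
   |r| ≥ 0.7 between the site's profile and the kinase's own, in correlated
   or anticorrelated (inhibitory-site) mode.

See `docs/methods.md` for assumptions, parameter rationale and limitations.

## Worked example

Run the numbered analysis scripts in order (or equivalently
`phosphodyn run-all --n-sites 5000 --seed 1 --out results/run`):

```
$ python analysis/01_simulate.py
simulated 10000 profiles (5000 sites x 2 stimuli)
planted 700 dynamic sites (14.0%), 3 kinases, 75 interaction edges -> results/simulated/

$ python analysis/02_global_variability.py
technical CV at t=0: 0.289 (n=9188)
phospho IQR heat: 0.540 at 0 min -> 0.666 at 20 min
phospho IQR cold: 0.538 at 0 min -> 0.580 at 20 min
nonphospho IQR heat stays near 0.190

$ python analysis/03_select_dynamic.py
9488 profiles after localization filter
9483 pass the 10-of-15 quantification rule
167 pass R^2 > 0.9; 2 removed for protein drift

$ python analysis/04_cluster.py
clustered 165 candidate profiles in 15 dimensions
fuzzifier m = 1.2695 (analytic estimate)
MCD elbow selects k = 11
142 profiles exceed membership 0.7 -> dynamic set

$ python analysis/05_classify.py
131 dynamic sites of 4744 classified
  heat_specific              84  (64.1% of dynamic)
  cold_specific              36  (27.5% of dynamic)
  temperature_independent     6  (4.6% of dynamic)
  bidirectional               5  (3.8% of dynamic)
category agreement with planted truth among detected dynamic sites: 51.1%

$ python analysis/06_kinase_substrates.py
KIN1: 3 candidates pass PPI >= 0.9 and |r| >= 0.7; 3 of 5 planted substrates recovered, ...
```

Reading the numbers: the measurement-noise CV at t = 0 matches the configured
0.29; the phosphopeptide FC distribution widens after the temperature shift
while the nonphospho baseline stays flat (the IQR pattern that signals a
genuine proteome-wide response); the strict cubic-R² filter passes only the
strongest planted responses (167 of 10,000 profiles), which the clustering
then condenses into a membership-filtered dynamic set; and the classification
is dominated by single-stimulus categories because a both-responsive site
whose second profile narrowly misses R² > 0.9 is read as stimulus-specific —
the end-to-end agreement figure (51%) quantifies exactly that, while the
classification stage itself recovers ≥ 90% given correct dynamic flags (see
the test suite).

## Input formats

* **Site tables** (`read_site_table`): a documented `simple` dialect
  (`site_id` as `PROT_S123_m1`, `stimulus`, log2 values `t0..t28`, optional
  probabilities `p0..p28`) and a MaxQuant "Phospho (STY)Sites"-style dialect
  (`Protein`, `Position`, `Amino acid`, linear `Ratio H/L <t>` / `Ratio M/L
  <t>`, `Localization prob <t>`).
* **Protein quantitation**: `protein`, `stimulus`, linear ratios `t0..t28`.
* **Kinase predictions**: `site_id`, `kinase`, `kinase_group`, `score`.
* **PPI edges**: `protein_a`, `protein_b`, `combined_score` (STRING-style).
* **Known target sites**: `kinase`, `protein`, `position`, `residue`.

Outputs are TSV tables plus a JSON run manifest recording every parameter,
seed and stage-by-stage record count.
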