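# Canonical pipeline configuration.
#
# `simulation` holds every generative parameter of the synthetic cohort;
# omitted keys fall back to the package defaults (study-sized cohort of
# 2393, per-allele 25(OH)D effects of the four instrument SNPs, marginal
# 25(OH)D distribution with median ~41 nmol/L).  `panel` supplies the GRS
# weights, which in a real analysis come from an external study; here the
# per-allele effects are reused as illustrative weights.

simulation:
  n_individuals: 2393
  seed: 42
  allele_freqs:
    rs12785878: 0.45
    rs10741657: 0.40
    rs2282679: 0.30
    rs6013897: 0.25
  per_allele_effects:
    rs12785878: 2.14
    rs10741657: 1.10
    rs2282679: 2.94
    rs6013897: 0.74
  vitd_intercept: 36.4
  vitd_noise_sd: 16.3
  confounder_effect_on_vitd: 5.0
  causal_log_or_per_nmol: -0.004
  confounder_log_or: 0.2
  outcome_baseline_log_odds: -0.63

analysis:
  orientation: vitd_decreasing   # report ORs per 25 nmol/L *decrease*
  bp_med_rule: include           # antihypertensive medication counts as abnormal BP
  scale_nmol_l: 25.0

panel:
  - {rsid: rs12785878, gene: DHCR7/NADSYN1, class: synthesis, effect_allele_orientation: vitd_increasing, weight: 2.14}
  - {rsid: rs10741657, gene: CYP2R1, class: synthesis, effect_allele_orientation: vitd_increasing, weight: 1.10}
  - {rsid: rs2282679, gene: GC, class: transport, effect_allele_orientation: vitd_increasing, weight: 2.94}
  - {rsid: rs6013897, gene: CYP24A1, class: catabolism, effect_allele_orientation: vitd_increasing, weight: 0.74}
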