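# Default calibration of the synthetic study generator.
#
# The design mirrors the animal experiment the analysis was built for:
# two inbred strains with opposite immune bias (C57BL/6 = Th1, BALB/c = Th2),
# sampled at days 0/7/15 of a DSS treatment course, control vs treated arm,
# three biological replicates per cell.
#
# Gut composition profiles are genus-level proportions over the five marker
# genera, ordered as listed under otu.taxa.  The treated profiles encode the
# published kinetics: Proteobacteria (Helicobacter) peaks at 32% of total
# abundance on day 15 in treated C57BL/6 and at 29% on day 7 in treated
# BALB/c, with Verrucomicrobia (Akkermansia) appearing only in the BALB/c
# recovery phase (day 15) while Bacteroidetes/Firmicutes rebound.

design:
  strains: ["C57BL/6", "BALB/c"]
  days: [0, 7, 15]
  arms: ["control", "treated"]
  n_per_group: 3

# Disease-severity trajectory per strain on treated arms, scaled 0..1.
# C57BL/6 worsens monotonically; BALB/c peaks at day 7 and partially
# recovers by day 15.  Controls are severity 0 throughout.
severity:
  "C57BL/6": {0: 0.0, 7: 0.6, 15: 1.0}
  "BALB/c": {0: 0.0, 7: 0.7, 15: 0.3}

otu:
  depth: 50000
  concentration: 200.0      # Dirichlet dispersion; larger = less overdispersed
  otus_per_genus: 3
  otu_split: [0.6, 0.3, 0.1]  # within-genus OTU abundance split
  # Five marker genera plus three minor-phylum genera whose collapse under
  # dysbiosis carries the diversity (Evenness) loss, as in real 16S data.
  taxa:
    - {genus: Bacteroides, phylum: Bacteroidetes}
    - {genus: Alistipes, phylum: Bacteroidetes}
    - {genus: Lachnospiraceae, phylum: Firmicutes}
    - {genus: Helicobacter, phylum: Proteobacteria}
    - {genus: Akkermansia, phylum: Verrucomicrobia}
    - {genus: Bifidobacterium, phylum: Actinobacteria}
    - {genus: Anaeroplasma, phylum: Tenericutes}
    - {genus: Mucispirillum, phylum: Deferribacteres}
  compositions:
    control:
      default: [0.26, 0.16, 0.38, 0.02, 0.03, 0.06, 0.05, 0.04]
    treated:
      "C57BL/6":
        0: [0.26, 0.16, 0.38, 0.02, 0.03, 0.06, 0.05, 0.04]
        7: [0.20, 0.13, 0.42, 0.20, 0.005, 0.02, 0.015, 0.01]
        15: [0.16, 0.10, 0.38, 0.32, 0.004, 0.012, 0.012, 0.012]
      "BALB/c":
        0: [0.26, 0.16, 0.38, 0.02, 0.03, 0.06, 0.05, 0.04]
        7: [0.17, 0.11, 0.38, 0.29, 0.004, 0.016, 0.015, 0.015]
        15: [0.23, 0.15, 0.34, 0.08, 0.12, 0.03, 0.03, 0.02]

# Log-normal feature layers.  Shifts are applied on the natural-log scale:
# pro-labelled features move up by pro_max_log_fc * severity, anti-labelled
# features down by anti_max_log_fc * severity, neutral features never move.
layers:
  transcript:
    n_pro: 30
    n_anti: 20
    n_neutral: 70
    baseline_log_mean_range: [2.0, 6.0]
    log_sd: 0.1
    pro_max_log_fc: 1.3862943611198906   # ln 4
    anti_max_log_fc: 1.0986122886681098  # ln 3
  serum_metabolite:
    n_pro: 10
    n_anti: 8
    n_neutral: 22
    baseline_log_mean_range: [0.0, 3.0]
    log_sd: 0.1
    pro_max_log_fc: 1.0986122886681098   # ln 3
    anti_max_log_fc: 0.6931471805599453
  cecal_metabolite:
    n_pro: 10
    n_anti: 8
    n_neutral: 22
    baseline_log_mean_range: [0.0, 3.0]
    log_sd: 0.1
    pro_max_log_fc: 1.0986122886681098
    anti_max_log_fc: 0.6931471805599453

# Metabolic-category map used for condition-level correlation analytics:
# pro-labelled metabolites are assigned to amino-acid/lipid metabolism,
# anti-labelled ones to carbohydrate/nucleotide metabolism, alternating.
categories:
  pro: [amino_acid_metabolism, lipid_metabolism]
  anti: [carbohydrate_metabolism, nucleotide_metabolism]

clinical:
  grade_noise: 1         # integer jitter applied to stool/blood grades
  weight_sd: 1.0         # gaussian jitter on percent weight change
  max_weight_loss: 18.0  # percent loss at severity 1
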