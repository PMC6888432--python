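# evoscape

Integrative molecular-evolution analysis of a protein family on a fixed
phylogeny, built around the proteins mutated in Rett and Rett-like syndromes
(MeCP2, CDKL5, FOXG1) but applicable to any aligned ortholog set. Given a
multiple sequence alignment, a tree, per-residue disorder and
phosphorylation-propensity tracks, a missense-variant table, ortholog
presence/absence data and a tissue expression table, the pipeline answers,
per reference (human) residue and per protein:

- **How fast does each site evolve?** Empirical-Bayes posterior mean rates
  under JTT with a discrete-gamma prior (K = 16 equal-probability
  categories), standardized to Z scores: for site *c* with category rates
  *r₁…r_K* and pruning likelihoods *L_c(r_k)*,

  r̂_c = Σ_k r_k L_c(r_k) / Σ_k L_c(r_k),  Z = (r̂ − mean r̂) / SD(r̂)

  with gaps and `X` treated as missing data and the gamma shape α estimated
  by maximum likelihood on [0.02, 20]. Z < 0 means slower-than-average
  evolution.
- **Which residues are (constrained) disordered?** IUPred-style scores
  (cutoff 0.5) mapped over the alignment in tree ladder order; disordered
  residues split into *constrained disorder* (Z < 0) and *flexible disorder*
  (Z ≥ 0), and the ordered/disordered rate distributions compared by a
  Mann-Whitney U test (exact by enumeration when both groups are ≤ 8).
- **Which phosphosites are conserved?** NetPhos-style scores ≥ 0.75 on S/T/Y
  call sites per sequence; an alignment column is conserved when ≥ 50% of
  all sequences in the alignment are positive (gaps count as negatives).
- **Where do pathogenic variants fall?** Each missense variant is joined to
  its domain, order/rate category and distance to the nearest conserved
  phosphosite, with site- and case-weighted contingency summaries.
- **When was each protein acquired?** Binary ortholog profiles (presence =
  Smith-Waterman score ≥ 150) clustered with Ward's method on Manhattan
  distances and cut into four clusters labeled by taxonomic depth
  (Class 1 chordate … Class 4 eukaryote).
- **Where is each protein specifically expressed?** A tissue is flagged when
  its TPM exceeds μ + 1.65 s of the protein's 37-tissue profile (population
  SD; 1.65 = one-sided 90% normal factor).

A synthetic-data generator reproduces all of these inputs with known ground
truth (true site rates, disorder blocks, planted phosphosites, profile
classes, expression spikes), so the whole pipeline is testable offline.

## Worked example

```sh
evoscape simulate --seed 11 --out bundle/
printf 'outdir: results\n' > config.yaml
evoscape run --config config.yaml --indir bundle/
python - <<'EOF'
import json
s = json.load(open("results/summary.json"))
od = s["order_disorder"]
print("alpha:", round(s["site_rates"]["alpha"], 3))
print("order vs disorder: p = %.3g, medians %0.2f / %0.2f"
      % (od["p_value"], od["median_disordered"], od["median_ordered"]))
print("conserved phosphosites:", s["ptm"]["n_conserved_reference_sites"],
      "of", s["ptm"]["n_reference_sites"])
print("classes:", s["profiles"]["class_labels"])
EOF
```

prints (seed 11):

```
alpha: 0.302
order vs disorder: p = 2.19e-07, medians -0.13 / -0.62
conserved phosphosites: 7 of 10
classes: {'1': 'Class1_chordate', '2': 'Class2_metazoan', '3': 'Class3_multicellular', '4': 'Class4_eukaryote'}
```

The estimated gamma shape is below the simulation's 0.5 because the bundle's
disordered blocks evolve 3x faster, adding rate variance; disordered
residues evolve significantly faster than ordered ones (higher median Z);
the planted conserved phosphosites (true conservation 0.9) pass the majority
rule while the weakly conserved ones (0.3) do not; and the four planted
phylogenetic-profile classes are recovered with their taxonomic labels.

Every stage is also available as a library function
(`evoscape.posterior_mean_rates`, `evoscape.conserved_columns`,
`evoscape.ward_cluster`, `evoscape.specificity_calls`, …) and as individual
subcommands (`evoscape rates`, `evoscape ptm`, `evoscape profile`,
`evoscape expression`, …).

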