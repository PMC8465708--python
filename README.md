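# hdcminer

Mining histamine-secretion operons in bacterial genomes, and testing whether
the species that carry them are over-represented in disease cohorts.

Gut bacteria can decarboxylate dietary histidine to histamine, an immune
mediator implicated in inflammatory bowel disease.  The genomic signature of
this trait is a compact gene cluster coupling a histidine decarboxylase
(*hdcA*, either the pyruvoyl-dependent or the PLP-dependent family) with a
histidine/histamine antiporter (*hdcP*; subtypes *gadC*, *aaxC*, *adiC*),
sometimes accompanied by the maturation factor *hdcB*, a histidyl-tRNA
synthetase (*hisRS*), or an arginine decarboxylase (*adiA*/*aaxB*) forming a
two-decarboxylase, one-transporter three-component system.  `hdcminer`
implements the in-silico screen for these clusters and the downstream
comparative statistics, driven entirely by standard file formats (GFF3,
HMMER3 domtblout, TSV) so it runs on real genome catalogs or on its own
synthetic data.

## What it does

1. **Role calling** — proteins get roles from profile-HMM hits: custom
   PLP-decarboxylase profile at e ≤ 1e-100; PF02329 (pyruvoyl *hdcA*),
   PTHR42770 (antiporter) and accessory profiles at e ≤ 1e-40; the smallest
   passing e-value wins.
2. **Cluster detection** — a locus where an *hdcA* and an antiporter lie
   fewer than three genes apart (≤ 2 intervening genes) seeds a cluster,
   which is greedily extended with nearby role-bearing genes and classified
   by architecture (e.g. `hdcA_pyr/antiporter/hdcB`), with flags for *hdcB*,
   *hisRS*, three-component systems and duplicated antiporters.
3. **Species prevalence** — a species with clusters in more than 50% of its
   strains is a histamine-secreting bacterium (HSB); with at most 50% it is
   strain-specific.
4. **Disease enrichment** — count tables are filtered (≥ 1M reads per
   sample; taxa must reach 0.01% relative abundance in ≥ 10% of samples),
   per-method differential-abundance calls are thresholded (DESeq2-like:
   log2FC > 1, q < 0.05; MaAsLin2-like: coef > 0.2, q < 0.05; LEfSe-like:
   LDA > 2, q < 0.001; HMP2-cohort variants included), and the proportion of
   disease-enriched species among HSB is compared with the proportion among
   all species by a one-tailed two-proportion Z-test with continuity
   correction:

   z = (|p₁ − p₂| − ½(1/n₁ + 1/n₂)) / √(π(1−π)(1/n₁ + 1/n₂)),  π pooled.

5. **Operon abundance** — per-sample operon depth in counts per million
   mapped reads (CPM = reads on operon / total mapped × 10⁶), compared
   between patients and controls by a one-sided Wilcoxon rank-sum test with
   continuity correction (exact enumeration for small tie-free samples).

A seeded synthetic-data module generates every input the pipeline consumes:
annotated genomes with operons planted at controlled strain prevalence plus
decoy hits, overdispersed negative-binomial count tables with planted
disease effects, and binomial operon read counts.

## Worked example

```sh
hdcminer run --seed 1 --outdir demo_out
```

prints one line per stage:

```
inputs: {'n_genomes': 30, 'n_genes': 975, 'n_hits': 315, 'n_truth_clusters': 24}
operon_mining: {'n_role_calls': 75, 'n_clusters': 24}
species_prevalence: {'n_species': 5, 'n_hsb': 4, 'n_strain_specific': 1, 'hsb_species': ['speciesA', 'speciesC', 'speciesD', 'speciesE']}
enrichment: {'n_samples': 60, 'n_species_tested': 200, 'n_enriched': 28, 'x_hsb': 20, 'n_hsb': 40, 'x_all': 28, 'n_all': 200, 'z': 4.979646071760521, 'p_one_tailed': 3.185032946887326e-07, 'label': '****'}
operon_abundance: {'n_samples': 60, 'median_cpm_control': 145.59881512727128, 'median_cpm_disease': 364.20424255298053, 'W': 1365.0, 'p_one_sided': 1.5099296795810785e-11}
```

Reading the numbers: the demo simulates 5 species × 6 strains with 24
planted operons of mixed architectures, and the miner recovers all 24 with
no false positives (`n_clusters` = `n_truth_clusters`).  Four species
exceed the 50% strain-prevalence rule and are flagged HSB; one (planted at
exactly 3/6) is strain-specific.  In the simulated cohort (30 patients,
30 controls, 200 species), 20 of 40 HSB species are disease-enriched versus
28 of 200 species overall, giving z = 4.98, one-tailed p = 3.2e-07 (****).
Disease samples also show ~2.5× higher operon CPM (364 vs 146 median),
rank-sum p = 1.5e-11.  All outputs are written as TSV reports plus a JSON
manifest under `demo_out/`.

Individual stages are available as subcommands (`simulate`,
`parse-annotations`, `find-clusters`, `prevalence`, `enrich`,
`operon-abundance`) and as library functions.

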