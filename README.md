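# txpod

Transcriptomic points of departure (tPODs) from concentration-response
gene-expression count data, with reverse dosimetry to administered
equivalent doses (AEDs) and comparison against apical in vivo points of
departure.

The pipeline:

1. **data_io** — read and validate count matrices, sample designs,
   probe→gene maps, GMT gene sets, a chemical inventory, an apical-POD
   reference table, and toxicokinetic parameters. Concentrations are in µM
   (0 = solvent control); CASRN is the join key across all tables.
2. **synthetic_data** — generate TempO-Seq-like negative-binomial count
   data with Hill-shaped log2 shifts and known ground truth (true BMCs,
   responsive probes, enriched gene sets), plus matched TK/apical tables
   with a designed log10 margin so end-to-end outlier flags are known.
3. **prefilter** — log2-CPM normalization (median-of-ratios size factors),
   then a Williams-style amalgamated trend test with permutation p-values
   (p < 0.05) and a max fold-change ≥ 1.5 gate.
4. **bmc_modeling** — fit Linear/Poly2/Power/Exp2–5 under a constant-variance
   normal likelihood, select by nested χ² (linear vs poly2) then lowest AIC,
   invert at BMR = 1 SD for the BMC, profile-likelihood BMCL/BMCU, apply the
   post-filters (fit p ≥ 0.1, BMCU/BMCL ≤ 40, BMC ≤ top concentration), and
   collapse probes to genes by lowest BMC.
5. **tpod_methods** — five tPODs per experiment: fifth-percentile gene
   (floor-index rule), first mode of the log10-BMC density, 25th-ranked
   gene, modified LCRD (lowest BMC of the largest consistent-response
   group, adjacent-ratio ≤ 1.66), and lowest qualifying gene-set median
   (≥ 3 genes and ≥ 5% of the set).
6. **ivive_aed** — three-compartment steady-state reverse dosimetry
   (well-stirred liver + renal GFR·fub clearance), Monte Carlo population
   variability, AED = tPOD / Css(95th quantile) at unit dose.
7. **comparison_report** — lowest AED per track (BMC-distribution vs
   gene-set), Log10Ratio = log10(apical POD) − log10(AED), outlier flag
   when negative, concordance and coverage summaries.

## CLI

```bash
txpod simulate --out sim/ --seed 1 --n-probes 3000
txpod prefilter --counts sim/counts.tsv --design sim/design.tsv \
    --chemical-id 100000-00-0 --out trend.tsv --seed 1
txpod fit-bmc --counts sim/counts.tsv --design sim/design.tsv \
    --trend trend.tsv --probe-map sim/probe_map.tsv \
    --chemical-id 100000-00-0 --out-probes bmc.tsv --out-genes genes.tsv
txpod derive-tpod --genes genes.tsv --gmt sim/gene_sets.gmt \
    --chemical-id 100000-00-0 --out tpods.tsv
txpod ivive --tpods tpods.tsv --tk tk.csv --out aeds.tsv --seed 1
txpod compare --aeds aeds.tsv --apical apical.csv --out-dir report/
txpod run-all --out report/ --seed 1          # simulated cohort, end to end
```

All thresholds (0.05 / 1.5 / 0.1 / 40 / BMR k / confidence, physiology and
Monte Carlo settings) live in a YAML config passed with `--config`; see
`txpod.config.PipelineConfig` for the schema and defaults.

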