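"""Reuse fitted models on a new dataset and export a QTL-ready BED.

Models are trained on one cohort, saved, reloaded, and applied to a
second cohort with the same genes but entirely new samples. Because
application standardizes with the *training* parameters, phenotype
dimensions correspond across cohorts. The result is exported as a
grouped-phenotype BED plus a phenotype-to-gene group file, the format
grouped cis-QTL mappers consume.
"""

import ddpheno as dp

train_cfg = dp.SimConfig(n_genes=4, n_samples=60, seed=21, structure_seed=100)
new_cfg = dp.SimConfig(n_genes=4, n_samples=35, seed=22, structure_seed=100)

train_src, _ = dp.simulate_coverage(train_cfg)
new_src, _ = dp.simulate_coverage(new_cfg)
gtf_text, _ = dp.simulate_annotation(train_cfg)
with open("scratch/example_t.gtf", "w") as fh:
    fh.write(gtf_text)
regions = dp.parse_gene_regions("scratch/example_t.gtf", 1000)

run_cfg = dp.RunConfig(target_mean_bins=48, n_calibration_genes=4,
                       n_binning_samples=60, seed=21)
schemes, _ = dp.define_bins(regions, train_src, run_cfg)
store = dp.fit_models(dp.bin_dataset(regions, schemes, train_src),
                      schemes, run_cfg)
dp.save_models(store, "scratch/models.zip")

# later / elsewhere: reload and apply to the new cohort
store = dp.load_models("scratch/models.zip")
raw_new = dp.bin_dataset(regions, schemes, new_src)
table = dp.apply_models(store, raw_new, run_cfg)
bed = dp.export_bed(table, {r.gene_id: r for r in regions},
                    "scratch/phenotypes.bed", "scratch/phenotypes.groups")
print(f"applied {len(store.models)} models to "
      f"{len(table.values.columns)} new samples")
print(f"BED rows (one per phenotype): {len(bed)}")
print(bed.iloc[:4, :6].to_string(index=False))
# Each row is one gene:PC phenotype positioned at the gene TSS; the
# group file ties phenotypes of a gene together for grouped mapping.
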