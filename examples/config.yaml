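# Demo pipeline config: generate all inputs synthetically and run every stage.
seed: 1
output_dir: darksip_out

inputs:
  synthetic:
    n_cells_per_depth: 60
  # Or point at your own tables instead:
  # roi: {path: fixtures/roi.tsv}
  # nitrif: {path: fixtures/nitrif.tsv}
  # gene_coverage: {path: fixtures/gene_coverage.tsv}
  # contig_hits: {path: fixtures/contig_hits.tsv}
  # profile: {path: fixtures/profile.tsv}

constants:
  copy_number: 1.1            # mean ureC copies per carrier genome
  yield_molC_per_molN: 0.09   # DIC fixed per N oxidized
  cell_content_fg_N: 10.0     # placeholder; set a site-appropriate value
  alpha: 0.05
  nox_floor_uM: 0.5           # exclude series below this mean NOx
  region_bounds_m: [0, 200, 1000, 4500]
  region_volumes_L:
    epipelagic: 1.0e+18
    mesopelagic: 4.0e+18
    bathypelagic: 1.0e+19
  label:
    urea: {amendment_nM: 50, label_purity: 0.98, ambient_nM: 50, n_per_molecule: 2}
    ammonium: {amendment_nM: 50, label_purity: 0.99, ambient_nM: 10, n_per_molecule: 1}

environment:
  sst_C: 12.0
  npp_mgC_m2_d: 500.0
  z_top_m: 100.0
  z_bottom_m: 4000.0
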