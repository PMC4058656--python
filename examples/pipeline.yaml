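# Annotated pipeline configuration for `catsom run --config pipeline.yaml`.
#
# Generate the input files first, e.g.:
#   catsom simulate blocks --n-aldehydes 78 --n-dicarbonyls 56 --seed 1 --out data/
#   catsom simulate refs   --n-signal 125 --n-background 375 --seed 1 --out data/

# --- inputs (must exist when the run starts) -------------------------------
aldehydes: data/aldehydes.smi        # SMILES + id, whitespace-delimited
dicarbonyls: data/dicarbonyls.smi
references: data/references.smi      # SMILES + id + semicolon class labels
# labels: data/labels.tsv            # optional; defaults to labels above

# --- outputs ----------------------------------------------------------------
outdir: out/profiling_run            # all artifacts + manifest land here

# --- analysis ---------------------------------------------------------------
target_class: kinase_like            # class whose top cluster seeds candidates
scaling: type-frequency              # CATS scaling: raw | type-frequency
seed: 42                             # single global seed; per-stage seeds are
                                     # derived as sha256("<seed>:<stage>") mod 2^31

# --- building-block selection filter ---------------------------------------
filter_criteria:
  max_mw: 300                        # Da, strict (<)
  max_alogp: 2                       # Crippen alogP, strict (<)
  forbidden_elements: [Br, I]
  require_single_functionality: true

# --- self-organizing map ----------------------------------------------------
som_width: 15                        # neurons per row
som_height: 20                       # rows; 15 x 20 = 300 clusters
som_cycles: 1000000                  # online sample presentations (10^6)
som_sigma0: 7.0                      # initial Gaussian neighborhood radius
som_sigma_end: 0.5                   # final radius (exponential decay)
som_alpha0: 0.5                      # initial learning rate
som_alpha_end: 0.01                  # final learning rate
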