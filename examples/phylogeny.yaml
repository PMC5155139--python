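# Example configuration for `paleobite run-phylogeny`.
#
# Generate a synthetic matrix first:
#   paleobite simulate matrix --seed 0 --out-prefix synthetic

phylogeny:
  matrix: synthetic_matrix.nex     # NEXUS or TNT xread
  replicates: 10                   # random-addition search replicates
  seed: 0
  bremer_window: 3                 # max extra steps examined for decay
  # alternative_trees:             # optional Templeton comparisons
  #   - alternative1.nwk
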