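# Default run configuration.
#
# Constants anchored to the study's printed measurement model and estimates:
#   - flow-cytometry lower detection limit: 2037 A.U.
#   - variance assigned below the limit: 2344 (A.U. scale)
#   - relative error of specific growth rates: 10%
#   - AD-polymerase dissociation constants: 0.8 mM (B42), 4 uM (B112),
#     200 nM (Gal4AD), 27 nM (VP16)
# All other kinetic constants are the package's calibrated defaults
# (see tfdyn.params.default_parameters and docs/methods.md).

network:
  variant: B42
  n_boxes: 4
  nop_n_factor: true        # multiply the steric factor N_OP by n
  pol_total_mode: moiety    # or: free_nuclear

measurement:
  s_f: 100.0                # A.U. per nM mature reporter (estimated scale)
  bg_f: 400.0               # autofluorescence background, A.U.
  detection_limit: 2037.0
  floor_variance: 2344.0
  s_m: 2.0                  # relative units per nM reporter mRNA
  growth_rel_error: 0.10

growth:                     # maximal specific growth rates (1/min) per medium
  SDC: 0.0046
  SGlyC: 0.0028
  SDP: 0.0030
  k_mmu: 23.0               # Hill half-saturation in total polymerase (nM)
  n_hmu: 2.0

estimation:
  seed: 1
  budget: 5000              # objective evaluations
  # free parameters default to the parameter set's free flags (45 total);
  # bounds default to +/- 3 decades around each default value

design:
  seed: 1
  noise: true

paths:
  out_dir: results
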