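# Desk-scale demo: 75 synthetic twin pairs, injected regions, 100 permutations.
seed: 7
simulate:
  n_probes: 4000
  injected_dmrs:
    - {n_probes: 4, delta: 0.3, direction: hyper}
    - {n_probes: 4, delta: 0.3, direction: hyper}
  injected_vmrs:
    - {n_probes: 4, var_ratio: 4.0}
    - {n_probes: 4, var_ratio: 4.0}
permutations:
  k: 100
enrichment:
  n_resample: 200
  n_boot: 200
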