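# Sample study configuration for `airimpute benchmark` / `airimpute reproduce`.
# Any omitted key keeps its default (full five-station 2192-day study,
# all six methods, three mechanisms, five rates, 10 replicates).
panel:
  n_days: 400       # days per station
  n_stations: 5
  seed: 3
mechanisms: [MCAR, MAR, MNAR]
rates: [0.05, 0.10, 0.20, 0.30, 0.40]
methods: [missforest, knn, pmm, em, bpca, chained_rf]
m: 20               # completions per multiple-imputation ensemble
replicates: 3
master_seed: 3
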