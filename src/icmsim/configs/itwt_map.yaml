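# Inferred-theoretical wild type (ITWT): frozen MAP reference parameter set.
# Fixed constants omitted here fall back to their library defaults.
variant: ITWT
lattice: {cells: 100}
free:
  Nanog_NANOG: 125
  Gata6_GATA6: 275
  Gata6_NANOG: 412
  Nanog_GATA6: 411
  Fgf4_NANOG: 552
  Gata6_AERK: 615
  Fgf4_GATA6: 95
  Nanog_AERK: 695
  tau_escape: 2303
  tau_exchange: 1380
  chi_auto: 0.39
  tau_pho_erk: 31379
  tau_doh_erk: 1025
  tau_pho_nanog: 18944
  tau_doh_nanog: 21361
  mean_init_mrna: 117
  mean_init_protein: 482
  tau_d_fgf4: 13158
  tau_d_mfgfr: 3456
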