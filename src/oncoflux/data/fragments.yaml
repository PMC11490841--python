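# Fragment registry: TBDMS (MTBSTFA) derivatives, M-57 ions, as commonly
# quantified in GC/MS 13C-tracing work.  Formulas are standard literature
# values for these derivatives, not instrument-verified for any particular
# run -- edit to match your own SIM method.
# n_tracer_carbons = carbons from the metabolite backbone (tracer-labellable).
pyruvate:
  formula: C6H12NO3Si
  n_tracer_carbons: 3
  note: MOX-1TBDMS, M-57
lactate:
  formula: C11H25O3Si2
  n_tracer_carbons: 3
  note: 2TBDMS, M-57
alanine:
  formula: C11H26NO2Si2
  n_tracer_carbons: 3
  note: 2TBDMS, M-57
glycine:
  formula: C10H24NO2Si2
  n_tracer_carbons: 2
  note: 2TBDMS, M-57
serine:
  formula: C16H38NO3Si3
  n_tracer_carbons: 3
  note: 3TBDMS, M-57
aspartate:
  formula: C18H40NO4Si3
  n_tracer_carbons: 4
  note: 3TBDMS, M-57
glutamate:
  formula: C19H42NO4Si3
  n_tracer_carbons: 5
  note: 3TBDMS, M-57
glutamine:
  formula: C19H43N2O3Si3
  n_tracer_carbons: 5
  note: 3TBDMS, M-57
citrate:
  formula: C26H55O7Si4
  n_tracer_carbons: 6
  note: 4TBDMS, M-57
succinate:
  formula: C12H25O4Si2
  n_tracer_carbons: 4
  note: 2TBDMS, M-57
fumarate:
  formula: C12H23O4Si2
  n_tracer_carbons: 4
  note: 2TBDMS, M-57
malate:
  formula: C18H39O5Si3
  n_tracer_carbons: 4
  note: 3TBDMS, M-57
alpha-ketoglutarate:
  formula: C14H28NO5Si2
  n_tracer_carbons: 5
  note: MOX-2TBDMS, M-57
asparagine:
  formula: C18H41N2O3Si3
  n_tracer_carbons: 4
  note: 3TBDMS, M-57
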