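# Named growth conditions as exchange-bound overrides (mmol/gDW/h, BiGG sign
# convention: negative = uptake). Ids follow the BiGG namespace used by
# iML1515 (E. coli) and iMM904 (S. cerevisiae).
aerobic:
  EX_glc__D_e: [-10, 1000]
  EX_o2_e: [-2, 1000]
anaerobic:
  EX_glc__D_e: [-10, 1000]
  EX_o2_e: [0, 1000]
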