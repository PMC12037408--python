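{
  "description": "Default region-replacement schemes for chimeric replacement mutagenesis: single non-identity parts, adjacent combinations and the full variable body. Shipped as a documented reconstruction; supply your own file to change the scheme set.",
  "schemes": [
    {"name": "S01", "parts": ["unpaired_8_9"]},
    {"name": "S02", "parts": ["d_arm"]},
    {"name": "S03", "parts": ["dt_loops"]},
    {"name": "S04", "parts": ["vloop"]},
    {"name": "S05", "parts": ["ac_stem"]},
    {"name": "S06", "parts": ["t_arm"]},
    {"name": "S07", "parts": ["unpaired_8_9", "d_arm"]},
    {"name": "S08", "parts": ["d_arm", "dt_loops"]},
    {"name": "S09", "parts": ["dt_loops", "t_arm"]},
    {"name": "S10", "parts": ["vloop", "ac_stem"]},
    {"name": "S11", "parts": ["ac_stem", "t_arm"]},
    {"name": "S12", "parts": ["unpaired_8_9", "d_arm", "dt_loops"]},
    {"name": "S13", "parts": ["d_arm", "dt_loops", "t_arm"]},
    {"name": "S14", "parts": ["vloop", "ac_stem", "t_arm"]},
    {"name": "S15", "parts": ["unpaired_8_9", "d_arm", "dt_loops", "vloop"]},
    {"name": "S16", "parts": ["unpaired_8_9", "d_arm", "dt_loops", "vloop", "ac_stem", "t_arm"]}
  ]
}
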