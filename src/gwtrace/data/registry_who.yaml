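# Drinking-water guideline limits (μg/L) and chronic oral reference doses
# (mg/kg/day) for the three study analytes.
limits:
  WHO:
    arsenic: 10
    antimony: 20
    selenium: 40
rfd:
  arsenic: 0.0003
  antimony: 0.0004
  selenium: 0.005
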