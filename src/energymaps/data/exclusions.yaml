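# Manual curation rules applied after the two-source consensus step.
# Hexokinase catalyzes the committed first step of glucose metabolism and
# therefore gates entry into both glycolysis and the pentose phosphate
# pathway; it is removed from both sets so each map reflects the pathway
# proper rather than the shared entry point.
exclusions:
  - gene: HK1
    pathways: [glycolysis, ppp]
    reason: hexokinase gates entry into both glycolysis and the PPP
  - gene: HK2
    pathways: [glycolysis, ppp]
    reason: hexokinase gates entry into both glycolysis and the PPP
  - gene: HK3
    pathways: [glycolysis, ppp]
    reason: hexokinase gates entry into both glycolysis and the PPP
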