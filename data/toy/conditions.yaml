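- label: day1
  c_product: 0.0
  knockouts:
  - ansa30
  measurements:
    consumption_g: 13.836
    dcw_g: 0.8
    hours: 24.0
    molecular_weight: 180.16
- label: day2
  c_product: 0.0013
  knockouts:
  - ansa30
  measurements:
    consumption_g: 17.598
    dcw_g: 1.1
    hours: 24.0
    molecular_weight: 180.16
- label: day3
  c_product: 0.0068
  knockouts:
  - ansa30
  measurements:
    consumption_g: 19.111
    dcw_g: 1.3
    hours: 24.0
    molecular_weight: 180.16
- label: day5
  c_product: 0.0084
  knockouts:
  - ansa30
  measurements:
    consumption_g: 31.132
    dcw_g: 1.2
    hours: 48.0
    molecular_weight: 180.16
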