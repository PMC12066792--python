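# Benchmark rule fixture in the style of an incidence-based national CC
# list: codes that are COMMON in the bundled synthetic cohort are listed as
# severe, regardless of their cost impact.  Crossed with hospital level and
# insurance type it yields up to 18 group labels, the shape of a
# national-standard grouping of this cohort.
cc_lookup:
  Z98: MCC
  L88: MCC
  G92: MCC
  C25: MCC
  D73: MCC
  R57: MCC
  I10: MCC
  J95: CC
  B44: CC
  Q12: CC
  I12: CC
  B49: CC
  S73: CC
  A41: CC
  B95: CC
  G97: nonCC
  T06: nonCC
  B37: nonCC
  F43: nonCC
  A40: nonCC
  D46: nonCC
default_label: B00
rules:
  - {when: {severity: MCC, hospital_level: tertiary, insurance: urban_employee}, label: B01}
  - {when: {severity: MCC, hospital_level: tertiary, insurance: urban_rural_resident}, label: B02}
  - {when: {severity: MCC, hospital_level: secondary, insurance: urban_employee}, label: B03}
  - {when: {severity: MCC, hospital_level: secondary, insurance: urban_rural_resident}, label: B04}
  - {when: {severity: MCC, hospital_level: primary, insurance: urban_employee}, label: B05}
  - {when: {severity: MCC, hospital_level: primary, insurance: urban_rural_resident}, label: B06}
  - {when: {severity: CC, hospital_level: tertiary, insurance: urban_employee}, label: B07}
  - {when: {severity: CC, hospital_level: tertiary, insurance: urban_rural_resident}, label: B08}
  - {when: {severity: CC, hospital_level: secondary, insurance: urban_employee}, label: B09}
  - {when: {severity: CC, hospital_level: secondary, insurance: urban_rural_resident}, label: B10}
  - {when: {severity: CC, hospital_level: primary, insurance: urban_employee}, label: B11}
  - {when: {severity: CC, hospital_level: primary, insurance: urban_rural_resident}, label: B12}
  - {when: {severity: nonCC, hospital_level: tertiary, insurance: urban_employee}, label: B13}
  - {when: {severity: nonCC, hospital_level: tertiary, insurance: urban_rural_resident}, label: B14}
  - {when: {severity: nonCC, hospital_level: secondary, insurance: urban_employee}, label: B15}
  - {when: {severity: nonCC, hospital_level: secondary, insurance: urban_rural_resident}, label: B16}
  - {when: {severity: nonCC, hospital_level: primary, insurance: urban_employee}, label: B17}
  - {when: {severity: nonCC, hospital_level: primary, insurance: urban_rural_resident}, label: B18}
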