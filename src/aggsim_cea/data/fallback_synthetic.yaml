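# SYNTHETIC fallback summary table.
#
# The analysis replaces summary statistics missing from a publication with
# values from a reference validation study whose raw statistics are not
# publicly available; this bundled stand-in carries plausible moderate
# knee-osteoarthritis magnitudes instead (WOMAC pain 0-20, function 0-68,
# stiffness 0-8; age and years since diagnosis in years).
means:
  pain: 10.0
  function: 34.0
  stiffness: 4.0
  age: 62.0
  years_since_oa: 8.0
sds:
  pain: 3.0
  function: 9.0
  stiffness: 1.2
  age: 8.0
  years_since_oa: 2.4
corr:
  - [1.0, 0.6, 0.5, 0.1, 0.1]
  - [0.6, 1.0, 0.5, 0.1, 0.1]
  - [0.5, 0.5, 1.0, 0.1, 0.1]
  - [0.1, 0.1, 0.1, 1.0, 0.3]
  - [0.1, 0.1, 0.1, 0.3, 1.0]
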