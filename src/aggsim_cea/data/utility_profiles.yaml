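# Utility-coefficient profiles for the linear WOMAC-to-utility mapping.
#
# The published regression equation this analysis relies on is external to the
# package and must be transcribed by the user into a profile of this form.
# The bundled "placeholder" profile is SYNTHETIC: coefficient magnitudes are
# merely plausible for a preference-based utility anchored near full health,
# and exist so that the simulation machinery can be exercised and tested.
profiles:
  placeholder:
    source: "synthetic placeholder profile - not a published regression fit"
    intercept: 0.875
    pain: -0.0165
    function: -0.0043
    stiffness: -0.0105
    age: -0.0005
    years_since_oa: -0.0013
    female: -0.0045
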