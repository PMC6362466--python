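# Synthetic scenario presets.  Each entry overrides the defaults of
# SyntheticConfig; unlisted keys keep their defaults (see simulate.py).
#
# "default" is the shipped analysis scenario: large enough for the fill-up
# bounds to sit in their large-sample regime while keeping an end-to-end
# run (including a random forest) to seconds.  "small" is a quick-look
# scenario for demos and smoke runs.  "registry_scale" matches the size of
# a one-year nine-registry case listing.
default:
  n_cases: 6000
  seed: 0
small:
  n_cases: 1500
  seed: 0
registry_scale:
  n_cases: 26017
  seed: 0
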