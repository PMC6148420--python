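# Example configuration for `corvgrowth run-all`.
#
# The per-recruit demographic values are ILLUSTRATIVE defaults for a
# short-lived sciaenid (M from a longevity-based rule with t_max = 9 y;
# generic isometric weight-length in kg and mm); replace them with stock-
# specific estimates for a real assessment.

# Map the canonical column names to your file's headers if they differ:
# column_map:
#   age: Age
#   length_mm: TL

max_age: 8

bolster:
  target_per_age: 200

per_recruit:
  M: 0.47            # natural mortality, 1/y
  E_OA: 0.825        # current annual exploitation rate of old adults
  E_YA: 0.0          # young adults (ages 2-4) assumed unexploited
  a_R: 2             # age at sexual maturity, y
  a_OA: 5            # age entering the old-adult stage, y
  A_max: 8           # oldest modelled age, y
  female_fraction: 0.5
  lw_a: 9.5e-9       # weight-length coefficient (kg per mm^lw_b)
  lw_b: 3.0          # weight-length exponent
  e_grid_step: 0.005
  extra_scenarios:
    # a fixed reference curve in addition to the fitted scenarios
    reference_vb:
      model: von_bertalanffy
      params: {L_inf: 1006.0, K: 0.23, t0: -0.5}
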