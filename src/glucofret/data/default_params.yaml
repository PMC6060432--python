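# Calibrated default parameters for the glucose kinetics model and the
# FRET sensor response.  Units: fluxes mM/min, saturation constants mM,
# time constants min.  Non-transgenic defaults are calibrated to give a
# relative-ratio slope of about -2 %/min in the 2-7 min window after a
# 2.5 -> 0.2 mM glucose restriction and about +10% after 50 min of a
# 2.5 -> 10 mM step.  Calibration values are defaults, not claims about
# any real recording; sensor affinity and dynamic range are conventions
# (k_d chosen as 0.7 mM; only relative ratios matter downstream).
kinetics:
  v_transport: 0.0732
  k_transport: 0.872
  v_glycolysis: 0.0202
  v_ppp: 0.0166
  v_hbp_max: 0.03
  k_consume: 0.0163
  tau_hk_inhibition: 18.0
  tau_hbp_transient: 8.0
  genotypes:
    nonTg:  {glycolysis_scale: 1.0, ppp_scale: 1.0, hbp_transient_scale: 0.0}
    3xTgAD: {glycolysis_scale: 1.75, ppp_scale: 0.25, hbp_transient_scale: 1.0}
sensor:
  k_d: 0.7
  r_min: 1.0
  r_max: 1.872
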