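# Default trait configuration: three soil NOB functional types.
#
# Units: concentrations (flexible-trait abscissae) in M; half-saturations
# in uM; v_max in uM (M biomass)^-1 s^-1; mu_max and mortality in s^-1.
#
# The flexible mu_max and K_M(O2) anchors of the mixotroph are published
# ecophysiological values for Nitrobacter hamburgensis-like organisms.
# The remaining values are a calibration consistent with the K/r contrast
# between Nitrospira (low half-saturations, slow growth) and Nitrobacter
# (high half-saturations, fast growth, much higher specific activity);
# see docs/methods.md for the calibration rationale.
provenance: reference run (3 types)
profiles:
  - name: Nitrospira
    strategy: K_chemolithotroph
    v_max_no2: 1500.0
    k_m_no2: 15.0
    k_m_o2: 10.0
    v_max_oc: 0.0
    k_m_oc: 500.0
    k_m_c: 5.0
    mu_max: 7.0e-6
    growth_yield: 0.04
    mortality: 3.0e-7
  - name: Nitrobacter_chemolitho
    strategy: r_chemolithotroph
    v_max_no2: 35000.0
    k_m_no2: 500.0
    k_m_o2: 18000.0
    v_max_oc: 0.0
    k_m_oc: 500.0
    k_m_c: 5.0
    mu_max: 1.6e-5
    growth_yield: 0.08
    mortality: 3.0e-7
  - name: Nitrobacter_mixo
    strategy: r_mixotroph
    v_max_no2: 2200.0
    k_m_no2: 500.0
    k_m_o2: 25.1
    v_max_oc: 10000.0
    k_m_oc: 500.0
    k_m_c: 5.0
    mu_max: 6.9e-6
    growth_yield: 0.08
    mortality: 3.0e-7
    flexible_mu_max:
      - [0.0, 6.9e-6]
      - [5.0e-3, 2.78e-5]
    flexible_k_m_o2:
      - [1.0e-4, 25.1]
      - [6.25e-3, 125.0]
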