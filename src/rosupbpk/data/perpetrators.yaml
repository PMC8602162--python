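# Perpetrator PK parameter sets and competitive inhibition constants.
#
# Provenance: "literature" marks a published in vitro inhibition constant
# (rifampicin vs OATP1B1/1B3: 0.63 uM, with 0.29 uM as a published
# alternative); all other entries are literature-plausible package
# defaults, overridable per study.
# Perpetrator PK is deliberately coarse 1-compartment superposition — the
# competitive-inhibition mechanism, not perpetrator fidelity, is the
# modelled content.  Ki values refer to unbound perpetrator concentration.

rifampicin:
  pk:
    molecular_weight_g_per_mol: 822.94
    cl_l_per_h: 7.0
    v1_l: 55.0
    ka_per_h: 1.15
    f_bio: 0.9
    fu: 0.2
  inhibition:
    - {target_process: OATP1B1_1B3, ki_umol_per_l: 0.63, provenance: literature}
    - {target_process: OATP2B1, ki_umol_per_l: 17.0, provenance: default}  # scaled for the systemic-unbound driving convention (intestinal uptake inhibition is luminal in reality)
    - {target_process: BCRP, ki_umol_per_l: 14.4, provenance: default}
    - {target_process: Pgp, ki_umol_per_l: 26.4, provenance: default}
    - {target_process: CYP2C9, ki_umol_per_l: 30.3, provenance: default}

gemfibrozil:
  pk:
    molecular_weight_g_per_mol: 250.34
    cl_l_per_h: 6.7
    v1_l: 14.0
    ka_per_h: 2.0
    f_bio: 0.98
    fu: 0.03
    metabolite_fraction: 0.3        # circulating 1-O-beta-glucuronide, molar
    metabolite_name: gemfibrozil_glucuronide
  inhibition:
    - {target_process: OATP1B1_1B3, ki_umol_per_l: 4.0, provenance: default}
    - {target_process: OAT3, ki_umol_per_l: 3.4, provenance: default}
    - {target_process: CYP2C9, ki_umol_per_l: 5.8, provenance: default}
    - {perpetrator: gemfibrozil_glucuronide, target_process: OATP1B1_1B3, ki_umol_per_l: 7.9, provenance: default}
    - {perpetrator: gemfibrozil_glucuronide, target_process: OAT3, ki_umol_per_l: 20.0, provenance: default}

probenecid:
  pk:
    molecular_weight_g_per_mol: 285.36
    cl_l_per_h: 1.3
    v1_l: 11.0
    ka_per_h: 1.0
    f_bio: 0.95
    fu: 0.12
  inhibition:
    - {target_process: OAT3, ki_umol_per_l: 5.4, provenance: default}
    - {target_process: OATP1B1_1B3, ki_umol_per_l: 60.0, provenance: default}
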