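# Reference parameter sets for the two physiological variables (CH = total
# cholesterol, mg/dL; DBP = diastolic blood pressure, mmHg), stratified by
# sex and risk-allele carrier status, as estimated on the Framingham original
# cohort.  Values are on the DISPLAY scale used in published tables:
# a_mu1 multiplied by 1e4, b_mu1 by 1e5, b_Y by 1e3; the loader converts to
# the natural scale.  These sets serve as generative defaults for the
# synthetic-cohort generator.
scale: display
parameters:
  CH:
    F:
      p1: 0.645
      noncarrier:
        ln_a_mu0: -7.59
        b_mu0: 0.086
        sigma2: 0.00
        a_mu1: -0.0037
        b_mu1: 0.0009
        a_Y: -0.093
        b_Y: 0.978
        a_f1: 223.99
        b_f1: 1.731
        c_f1: -0.0583
        sigma0: 39.05
        sigma1: 14.30
      carrier:
        ln_a_mu0: -6.12
        b_mu0: 0.058
        sigma2: 0.00
        a_mu1: -0.0071
        b_mu1: 0.0023
        a_Y: -0.138
        b_Y: 1.204
        a_f1: 244.08
        b_f1: 2.645
        c_f1: -0.0772
        sigma0: 49.14
        sigma1: 22.21
    M:
      p1: 0.666
      noncarrier:
        ln_a_mu0: -6.61
        b_mu0: 0.081
        sigma2: 0.00
        a_mu1: -0.0141
        b_mu1: 0.0035
        a_Y: -0.090
        b_Y: 0.644
        a_f1: 229.18
        b_f1: -0.588
        c_f1: -0.0239
        sigma0: 38.19
        sigma1: 13.60
      carrier:
        ln_a_mu0: -4.89
        b_mu0: 0.045
        sigma2: 0.06
        a_mu1: -0.0177
        b_mu1: 0.0044
        a_Y: -0.167
        b_Y: 1.705
        a_f1: 253.78
        b_f1: -0.055
        c_f1: -0.0379
        sigma0: 48.24
        sigma1: 22.30
  DBP:
    F:
      p1: 0.634
      noncarrier:
        ln_a_mu0: -8.37
        b_mu0: 0.122
        sigma2: 0.00
        a_mu1: 0.1767
        b_mu1: -0.0135
        a_Y: -0.149
        b_Y: 0.000
        a_f1: 78.60
        b_f1: 0.245
        c_f1: -0.0117
        sigma0: 8.96
        sigma1: 4.96
      carrier:
        ln_a_mu0: -6.62
        b_mu0: 0.091
        sigma2: 0.00
        a_mu1: -0.0886
        b_mu1: 0.0269
        a_Y: -0.135
        b_Y: 0.000
        a_f1: 87.62
        b_f1: 0.207
        c_f1: -0.0133
        sigma0: 14.69
        sigma1: 6.44
    M:
      p1: 0.640
      noncarrier:
        ln_a_mu0: -6.99
        b_mu0: 0.101
        sigma2: 0.00
        a_mu1: -0.4053
        b_mu1: 0.1013
        a_Y: -0.154
        b_Y: 0.000
        a_f1: 82.15
        b_f1: 0.050
        c_f1: -0.0096
        sigma0: 8.53
        sigma1: 4.86
      carrier:
        ln_a_mu0: -5.35
        b_mu0: 0.073
        sigma2: 0.00
        a_mu1: -0.4233
        b_mu1: 0.1058
        a_Y: -0.152
        b_Y: 0.000
        a_f1: 89.87
        b_f1: 0.156
        c_f1: -0.0130
        sigma0: 13.53
        sigma1: 6.55
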