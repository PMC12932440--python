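# Surgical-menopause parameter set, short-term calibration (data <= 15 years
# post-surgery). kappa_E/k_syn are day^-1; eta_surg/omega_surg are
# dimensionless fold-increases; tau is a relaxation rate in day^-1.
kappa_E: 6.1996       # estrogen degradation rate post-surgery
k_syn: 0.6            # residual estrogen synthesis rate post-surgery
eta_surg: 5.0         # peak fold-increase of osteocyte apoptosis at surgery
tau: 9.7e-3           # relaxation rate of the surgery effects
omega_surg: 1.86      # peak fold-increase of osteoclast differentiation
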