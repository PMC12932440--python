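# Surgical-menopause parameter set, long-term calibration (data up to 30 years
# post-surgery). tau = 0 makes the surgery effects permanent.
kappa_E: 6.1996
k_syn: 0.6
eta_surg: 0.4174
tau: 0.0
omega_surg: 0.2155
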