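# Natural-menopause (baseline) parameter set for the BMU bone-remodeling model.
# Rates are day^-1, thresholds are dimensionless (scaled species units),
# tau_E is in years (converted to days on ingestion), t_m is in days on the
# simulation clock (30 years after the default simulation start).
omega_PC: 0.93        # differentiation rate, preosteoclast -> osteoclast
omega_PB: 0.32        # differentiation rate, preosteoblast -> osteoblast
omega_B: 6.4e-4       # differentiation rate, osteoblast -> osteocyte
eta_B: 8.678e-3       # osteoblast apoptosis rate
eta_C: 1.096e-4       # osteoclast apoptosis rate
eta_S: 1.1e-4         # osteocyte apoptosis rate (baseline)
lambda_B: 1.29e-6     # first-order bone formation rate
lambda_C: 3.82e-6     # first-order bone resorption rate
kappa_Sc: 0.05        # sclerostin degradation rate
tau_E: 2.6            # characteristic time of natural estrogen decline [years]
e_PC: 0.2556          # estrogen threshold, inhibition of PC -> C
e_Sc: 10.59           # estrogen threshold, inhibition of sclerostin production
sc_PC: 8.6e6          # sclerostin threshold, activation of PC -> C
sc_PB: 1.63e2         # sclerostin threshold, inhibition of PB -> B
sc_Omega: 3.04e3      # sclerostin threshold, inhibition of bone formation
r_Omega: 1.02e3       # resorption-factor threshold in the density equation
nu_Omega: 1.08e3      # maximum relative effect of resorption on formation
BMC0: 0.8             # bone mineral content scale (BMD = BMC0 * Bd)
t_m: 10950            # menopause onset [days]
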