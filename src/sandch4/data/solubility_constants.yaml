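# Gas-solubility fit constants, keyed by gas id and unit convention.
#
# Conventions:
#   bunsen         : ln(beta) = A1 + A2*(100/T) + A3*ln(T/100)
#                    + S*(B1 + B2*(T/100) + B3*(T/100)^2)
#                    beta is the dimensionless volumetric Bunsen coefficient
#                    (L gas at STP per L solution per atm partial pressure).
#   nmol-per-L-atm : ln(C) = ln(f_G) + A1 + A2*(100/T) + A3*ln(T/100) + A4*(T/100)
#                    + S*(B1 + B2*(T/100) + B3*(T/100)^2)
#                    C is the atmospheric equilibrium concentration in nmol L^-1
#                    for a moist atmosphere at 1 atm total pressure (the
#                    100%-humidity correction is built into the fit).
#   mol-per-L-atm  : ln(K0) = A1 + A2*(100/T) + A3*ln(T/100)
#                    + S*(B1 + B2*(T/100) + B3*(T/100)^2)
#                    K0 is the aqueous-phase solubility in mol L^-1 atm^-1.
#
# CH4 constants follow the Wiesenburg & Guinasso (1979) fits; CO2 K0
# constants follow the Weiss (1974) fit in the same functional form.
ch4:
  bunsen:
    A1: -67.1962
    A2: 99.1624
    A3: 27.9015
    B1: -0.072909
    B2: 0.041674
    B3: -0.0064603
  nmol-per-L-atm:
    A1: -415.2807
    A2: 596.8104
    A3: 379.2599
    A4: -62.0757
    B1: -0.059160
    B2: 0.032174
    B3: -0.0048198
co2:
  mol-per-L-atm:
    A1: -58.0931
    A2: 90.5069
    A3: 22.2940
    B1: 0.027766
    B2: -0.025888
    B3: 0.0050578
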