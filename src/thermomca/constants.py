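"""Physical constants and process conditions.

All Gibbs energies in the package are transformed standard values (kJ/mol)
at the intracellular condition (pH 7.5, ionic strength 0.15 M); no on-the-fly
Legendre transforms are performed. Concentrations are stored in mM and
converted to mol/L wherever a log-concentration enters a thermodynamic
expression (standard state 1 M).
"""

#: Universal gas constant, kJ mol^-1 K^-1
R = 8.314462618e-3

#: Process temperature, K (37 degrees C)
T_DEFAULT = 310.15

#: R*T at the default temperature, kJ mol^-1
RT_DEFAULT = R * T_DEFAULT

#: mM -> mol/L
MM_TO_M = 1e-3
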