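"""Physical constants and unit conventions.

Internal units follow the MD convention: energies in kJ/mol, time in ps,
temperatures in K, λ and environment coordinates dimensionless.  Fictitious
λ masses are expressed in kJ·mol⁻¹·ps² per (λ-unit)², so literature values
such as m_λ = 5, 750 or 1500 can be used verbatim.
"""

#: Boltzmann constant, kJ·mol⁻¹·K⁻¹.
KB = 0.0083144621

#: ln(10), used throughout the pH ↔ free-energy conversions.
LN10 = 2.302585092994046
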