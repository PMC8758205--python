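"""Fixed physical constants (CODATA exact values, SI)."""

BOLTZMANN = 1.380649e-23
"""Boltzmann constant k_B (J/K)."""

AVOGADRO = 6.02214076e23
"""Avogadro constant N_A (1/mol)."""
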