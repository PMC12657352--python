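"""Unit conversions between SI and the conventional hemodynamic units.

Pressures are reported in mmHg, flows in mL/s and resistances in
mmHg·s·mL⁻¹ throughout the public API; geometry is entered in cm.
Constitutive coefficients are derived from the SI formulas and converted
once, so every quantity the solvers iterate on is O(1).
"""

PA_PER_MMHG = 133.322
M_PER_CM = 1e-2
M3_PER_ML = 1e-6


def resistance_si_to_mmhg_ml(r_si: float) -> float:
    """Pa·s·m⁻³ → mmHg·s·mL⁻¹."""
    return r_si * M3_PER_ML / PA_PER_MMHG


def quad_coeff_si_to_mmhg_ml(k_si: float) -> float:
    """Pa·s²·m⁻⁶ → mmHg·s²·mL⁻²."""
    return k_si * M3_PER_ML**2 / PA_PER_MMHG
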