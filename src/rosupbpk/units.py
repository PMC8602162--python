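"""Unit conversions.

Internal state is in µmol, concentrations in µmol/L, time in h.  Doses are
entered in mg and plasma concentrations reported in ng/mL; both conversions
go through the molecular weight (g/mol), since
1 µmol/L × MW g/mol = MW µg/L = MW ng/mL.
"""

MIN_PER_H = 60.0
ML_PER_L = 1000.0


def mg_to_umol(mg: float, molecular_weight: float) -> float:
    """Convert a mass dose in mg to µmol."""
    if molecular_weight <= 0:
        raise ValueError("molecular_weight must be positive")
    return mg * 1000.0 / molecular_weight


def umol_to_mg(umol: float, molecular_weight: float) -> float:
    return umol * molecular_weight / 1000.0


def umol_per_l_to_ng_per_ml(conc, molecular_weight: float):
    """µmol/L → ng/mL (works element-wise on arrays)."""
    return conc * molecular_weight


def ng_per_ml_to_umol_per_l(conc, molecular_weight: float):
    return conc / molecular_weight


def l_per_h_to_ml_per_min(clearance: float) -> float:
    """Clearance L/h → mL/min."""
    return clearance * ML_PER_L / MIN_PER_H
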