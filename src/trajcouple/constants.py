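"""Physical constants and unit conventions.

All lengths are Å, times ns, energies kcal/mol, temperatures K throughout the
package; conversions happen at I/O boundaries only.
"""

#: Boltzmann constant in kcal/(mol·K); single source of truth for the
#: free-energy-surface and interaction-entropy computations.
KB_KCAL_MOL_K: float = 0.0019872041

#: Simulation temperature the analyses default to (physiological, K).
DEFAULT_TEMPERATURE_K: float = 310.0

#: Atomic masses (amu) for elements that occur in protein/ligand systems.
#: Used when a coordinate file carries no mass information.
ELEMENT_MASSES = {
    "H": 1.008,
    "D": 2.014,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "NA": 22.990,
    "MG": 24.305,
    "P": 30.974,
    "S": 32.06,
    "CL": 35.45,
    "K": 39.098,
    "CA": 40.078,
    "FE": 55.845,
    "ZN": 65.38,
    "BR": 79.904,
    "I": 126.904,
}
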