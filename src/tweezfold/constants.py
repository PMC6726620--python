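"""Physical constants and shared defaults (units: s, nm, pN, K, kcal/mol)."""

# 1 J = 1e21 pN·nm, so kB = 1.380649e-23 J/K = 1.380649e-2 pN·nm/K.
KB_PN_NM = 1.380649e-2

#: Gas constant in kcal/(mol·K).
R_KCAL = 1.9872e-3

#: Default experimental temperature (20 °C room), K.
DEFAULT_TEMPERATURE = 293.15

#: Contour length per amino acid, nm (crystallographic convention).
L_AA_NM = 0.365

#: Default persistence length of unfolded polypeptide, nm.
PERSISTENCE_PROTEIN_NM = 0.65

#: Default effective DNA-handle worm-like chain (2 x (350+30) bp handles
#: lumped into one chain): contour and persistence, nm.
HANDLE_CONTOUR_NM = 260.0
HANDLE_PERSISTENCE_NM = 10.0


def kbt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy kB*T in pN·nm (~4.05 pN·nm at 293.15 K)."""
    return KB_PN_NM * temperature
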