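"""Physical constants and geometry tables used across the package.

All energies are in kcal/mol, distances in Angstrom, temperatures in
kelvin unless a function states otherwise.
"""

#: Gas constant, kcal mol^-1 K^-1.
R_GAS = 1.9872e-3

#: Additive offset between Celsius and kelvin scales.
CELSIUS_OFFSET = 273.15


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + CELSIUS_OFFSET


def kelvin_to_celsius(t_k: float) -> float:
    return t_k - CELSIUS_OFFSET


# ---------------------------------------------------------------------------
# Ideal peptide-backbone internal coordinates (poly-alanine builder).
# Bond lengths (A) and angles (deg) follow standard Engh-Huber-like values.
# The amide hydrogen is placed along the bisector of the N->C(i-1) and
# N->CA directions, in the peptide plane.
# ---------------------------------------------------------------------------
BACKBONE_GEOMETRY = {
    "bond_N_CA": 1.458,
    "bond_CA_C": 1.525,
    "bond_C_N": 1.329,   # peptide bond
    "bond_C_O": 1.231,
    "bond_N_H": 1.010,
    "bond_CA_CB": 1.521,
    "angle_C_N_CA": 121.7,
    "angle_N_CA_C": 111.2,
    "angle_CA_C_N": 116.2,
    "angle_CA_C_O": 120.8,
    "angle_N_CA_CB": 110.4,
    "omega": 180.0,      # trans peptide
}

# ---------------------------------------------------------------------------
# Hydrogen-bond energy function (Mayo-style distance/angle potential).
# E = HB_V0 * [5 (R0/R)^12 - 6 (R0/R)^10] * cos^2(theta) * exp(-(pi-theta)^6)
#     * cos^2(phi)
# with R the donor-acceptor distance, theta the donor-H-acceptor angle and
# phi the H-acceptor-antecedent angle.  Candidates are screened by the
# distance/angle cutoffs below; only favorable (E < 0) bonds are kept.
# ---------------------------------------------------------------------------
HB_V0 = 8.0          # kcal/mol well depth scale
HB_R0 = 2.8          # A, optimal donor-acceptor distance
HB_DA_CUTOFF = 3.6   # A, maximum donor-acceptor distance
HB_THETA_MIN = 90.0  # deg, minimum donor-H-acceptor angle
HB_MIN_STRENGTH = 0.01  # kcal/mol; weaker contacts are not constraints

# ---------------------------------------------------------------------------
# Hydrophobic tether rule: carbon/sulfur atom pairs from residues at least
# two apart in sequence, within (r_vdw_i + r_vdw_j + HYDROPHOBIC_SLACK).
# United-atom van der Waals radii (attached hydrogens subsumed into the
# heavy atom) keep the rule usable on H-less carbon frameworks.
# ---------------------------------------------------------------------------
VDW_RADII = {"C": 1.9, "S": 1.8}
HYDROPHOBIC_SLACK = 0.25
HYDROPHOBIC_MIN_SEQ_SEP = 2

# Covalent radii (A) for distance-based bond inference when a structure
# carries no explicit connectivity.
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
}
COVALENT_SLACK = 0.40

# Body-and-bar constraint multiplicities.
BARS_COVALENT = 5
BARS_HBOND = 5
BARS_HYDROPHOBIC = 2
DOF_PER_BODY = 6

# Linear map between the dilution energy E (kcal/mol, positive) and
# temperature: T(K) = E_TO_T_INTERCEPT + E_TO_T_SLOPE * E.
E_TO_T_INTERCEPT = 300.0
E_TO_T_SLOPE = 20.0
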