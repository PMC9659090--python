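"""Residue-level constant tables used throughout the package.

All masses are monoisotopic and in Da. The hydropathy scale is the
Kyte-Doolittle scale (the scale that defines the GRAVY score). The pKa
set is the EMBOSS set used by ``iep``; it is exposed as plain data so a
different published set can be passed to the pI solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

PROTON_MASS = 1.007276
WATER_MASS = 18.010565

#: Kyte-Doolittle hydropathy values for the 20 canonical residues.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Monoisotopic residue masses (peptide-bond residues, i.e. minus water).
MONOISOTOPIC_MASS: dict[str, float] = {
    "A": 71.037114, "R": 156.101111, "N": 114.042927, "D": 115.026943,
    "C": 103.009185, "E": 129.042593, "Q": 128.058578, "G": 57.021464,
    "H": 137.058912, "I": 113.084064, "L": 113.084064, "K": 128.094963,
    "M": 131.040485, "F": 147.068414, "P": 97.052764, "S": 87.032028,
    "T": 101.047679, "W": 186.079313, "Y": 163.063329, "V": 99.068414,
}

#: EMBOSS pKa values. Terminal groups keyed by sentinel names; side
#: chains keyed by residue letter. Positive groups: N-terminus, K, R, H.
#: Negative groups: C-terminus, D, E, C, Y.
EMBOSS_PKA: dict[str, float] = {
    "n_term": 8.6,
    "c_term": 3.6,
    "C": 8.5,
    "D": 3.9,
    "E": 4.1,
    "H": 6.5,
    "K": 10.8,
    "R": 12.5,
    "Y": 10.1,
}

POSITIVE_SIDE_CHAINS = frozenset("KRH")
NEGATIVE_SIDE_CHAINS = frozenset("DECY")

CARBAMIDOMETHYL_DELTA = 57.021464


@dataclass(frozen=True)
class Modification:
    """A residue modification parsed from a lowercase sequence letter.

    ``charge_as`` names the residue whose ionizable side chain the
    modified residue should contribute to net-charge/pI calculations
    (deamidated Asn gains a carboxylate, so it titrates like Asp).
    ``None`` means the parent residue's own group is kept.
    """

    name: str
    parent: str
    mass_delta: float
    charge_as: str | None = None


#: Lowercase letter -> modification, following common search-engine
#: export notation: oxidation of Met, deamidation of Asn/Gln, and the
#: carbamidomethylation-propionylation of Lys used in biotinylation
#: workflows.
LOWERCASE_MODIFICATIONS: dict[str, Modification] = {
    "m": Modification("Oxidation", "M", 15.994915),
    "n": Modification("Deamidation", "N", 0.984016, charge_as="D"),
    "q": Modification("Deamidation", "Q", 0.984016, charge_as="E"),
    "k": Modification("Carbamidomethyl-propionyl", "K", 113.047679),
}


@dataclass(frozen=True)
class ResidueScales:
    """Bundle of residue-level scales; swap fields to change conventions."""

    hydropathy: dict[str, float] = field(default_factory=lambda: dict(KYTE_DOOLITTLE))
    monoisotopic_mass: dict[str, float] = field(default_factory=lambda: dict(MONOISOTOPIC_MASS))
    pka: dict[str, float] = field(default_factory=lambda: dict(EMBOSS_PKA))
    modifications: dict[str, Modification] = field(
        default_factory=lambda: dict(LOWERCASE_MODIFICATIONS)
    )
    fixed_cys_carbamidomethyl: bool = True

    def __post_init__(self) -> None:
        residues = set(KYTE_DOOLITTLE)
        if set(self.hydropathy) != residues:
            raise ValueError("hydropathy scale must cover exactly the 20 canonical residues")
        if set(self.monoisotopic_mass) != residues:
            raise ValueError("mass scale must cover exactly the 20 canonical residues")
        for group, value in self.pka.items():
            if not 0.0 < value < 14.0:
                raise ValueError(f"pKa for {group} outside (0, 14): {value}")


DEFAULT_SCALES = ResidueScales()
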