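"""Physicochemical descriptors of (modified) peptide sequences.

Peptide identification exports write variable modifications as lowercase
letters inside the sequence string (``LGKIIINNKnFDK`` carries a
deamidated Asn at position 10). This module parses that notation and
derives the descriptor set used for platform comparisons: length,
monoisotopic mass, precursor m/z, GRAVY, pI and mass/length ratio.

The pI is the root of the Henderson-Hasselbalch net-charge function,
found by bisection; the pKa set is configurable through
:class:`~orthosep.scales.ResidueScales` because exported pI values
depend on the convention chosen upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .scales import (
    DEFAULT_SCALES,
    NEGATIVE_SIDE_CHAINS,
    POSITIVE_SIDE_CHAINS,
    PROTON_MASS,
    WATER_MASS,
    CARBAMIDOMETHYL_DELTA,
    ResidueScales,
)

_CANONICAL = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class PeptideSequence:
    """A parsed peptide: canonical residues plus per-position modifications.

    ``modifications`` maps 1-based positions to modification names as
    registered in the residue scales.
    """

    residues: str
    modifications: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("peptide must contain at least one residue")
        bad = [r for r in self.residues if r not in _CANONICAL]
        if bad:
            raise ValueError(f"non-canonical residue(s) {bad!r} in {self.residues!r}")
        for pos in self.modifications:
            if not 1 <= pos <= len(self.residues):
                raise ValueError(f"modification position {pos} outside 1..{len(self.residues)}")

    def __len__(self) -> int:
        return len(self.residues)

    def format(self, scales: ResidueScales = DEFAULT_SCALES) -> str:
        """Render back to the lowercase-notation string (parse round-trip)."""
        letter_for = {
            (mod.parent, mod.name): letter for letter, mod in scales.modifications.items()
        }
        out = []
        for i, res in enumerate(self.residues, start=1):
            name = self.modifications.get(i)
            if name is None:
                out.append(res)
            else:
                out.append(letter_for[(res, name)])
        return "".join(out)


@dataclass(frozen=True)
class PeptideProperties:
    length: int
    mass: float
    mz: float
    gravy: float
    pi: float
    mass_length_ratio: float


def parse_sequence(raw: str, scales: ResidueScales = DEFAULT_SCALES) -> PeptideSequence:
    """Parse a modified-sequence string.

    Uppercase letters are unmodified residues; lowercase letters are
    looked up in the scales' lowercase-modification table. Unknown
    letters are rejected with their 1-based position.
    """
    if not raw:
        raise ValueError("empty sequence string")
    residues = []
    mods: dict[int, str] = {}
    for pos, ch in enumerate(raw, start=1):
        if not ch.isalpha():
            raise ValueError(f"non-letter character {ch!r} at position {pos}")
        if ch.isupper():
            if ch not in _CANONICAL:
                raise ValueError(f"unknown residue {ch!r} at position {pos}")
            residues.append(ch)
        else:
            mod = scales.modifications.get(ch)
            if mod is None:
                raise ValueError(f"no modification mapping for lowercase {ch!r} at position {pos}")
            residues.append(mod.parent)
            mods[pos] = mod.name
    return PeptideSequence("".join(residues), mods)


def peptide_mass(p: PeptideSequence, scales: ResidueScales = DEFAULT_SCALES) -> float:
    """Monoisotopic mass in Da, including water and modification deltas.

    Carbamidomethylation of Cys is applied as a fixed modification when
    the scales say so (the default for alkylated tryptic digests).
    """
    mass = WATER_MASS + sum(scales.monoisotopic_mass[r] for r in p.residues)
    if scales.fixed_cys_carbamidomethyl:
        mass += CARBAMIDOMETHYL_DELTA * p.residues.count("C")
    delta_for = {(m.parent, m.name): m.mass_delta for m in scales.modifications.values()}
    for pos, name in p.modifications.items():
        mass += delta_for[(p.residues[pos - 1], name)]
    return mass


def gravy(p: PeptideSequence, scales: ResidueScales = DEFAULT_SCALES) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value per residue.

    Modified residues contribute their parent residue's hydropathy.
    """
    return sum(scales.hydropathy[r] for r in p.residues) / len(p)


def net_charge(p: PeptideSequence, ph: float, scales: ResidueScales = DEFAULT_SCALES) -> float:
    """Net charge at a given pH (Henderson-Hasselbalch sum over groups).

    Monotonically non-increasing in pH, which guarantees the bisection
    in :func:`isoelectric_point` converges to the unique root.
    """
    charge_residue = list(p.residues)
    charge_as = {
        (m.parent, m.name): m.charge_as
        for m in scales.modifications.values()
        if m.charge_as is not None
    }
    for pos, name in p.modifications.items():
        alt = charge_as.get((p.residues[pos - 1], name))
        if alt is not None:
            charge_residue[pos - 1] = alt

    pka = scales.pka
    total = 1.0 / (1.0 + 10.0 ** (ph - pka["n_term"]))
    total -= 1.0 / (1.0 + 10.0 ** (pka["c_term"] - ph))
    for r in charge_residue:
        if r in POSITIVE_SIDE_CHAINS and r in pka:
            total += 1.0 / (1.0 + 10.0 ** (ph - pka[r]))
        elif r in NEGATIVE_SIDE_CHAINS and r in pka:
            total -= 1.0 / (1.0 + 10.0 ** (pka[r] - ph))
    return total


def isoelectric_point(
    p: PeptideSequence,
    scales: ResidueScales = DEFAULT_SCALES,
    tol: float = 1e-4,
) -> float:
    """pH of zero net charge, by bisection on [0, 14].

    Iterates until both the net charge is below ``tol`` and the bracket
    is narrower than 1e-6 pH units, so the returned pH is accurate in
    its own right, not merely flat in charge.
    """
    lo, hi = 0.0, 14.0
    mid = 7.0
    while hi - lo > 1e-6 or abs(net_charge(p, mid, scales)) >= tol:
        mid = 0.5 * (lo + hi)
        if hi - lo < 1e-12:
            break
        if net_charge(p, mid, scales) > 0:
            lo = mid
        else:
            hi = mid
    return mid


def compute_properties(
    p: PeptideSequence, z: int, scales: ResidueScales = DEFAULT_SCALES
) -> PeptideProperties:
    """Full descriptor set for a parsed peptide at charge ``z`` (>= 1)."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    mass = peptide_mass(p, scales)
    return PeptideProperties(
        length=len(p),
        mass=mass,
        mz=(mass + z * PROTON_MASS) / z,
        gravy=gravy(p, scales),
        pi=isoelectric_point(p, scales),
        mass_length_ratio=mass / len(p),
    )


def properties_table(sequences, charges, scales: ResidueScales = DEFAULT_SCALES):
    """Descriptor DataFrame for paired (modified sequence, charge) inputs.

    Columns: sequence, charge, length, mass, mz, gravy, pi,
    mass_length_ratio — the shared TSV property schema.
    """
    import pandas as pd

    rows = []
    for raw, z in zip(sequences, charges, strict=True):
        props = compute_properties(parse_sequence(raw, scales), int(z), scales)
        rows.append(
            {
                "sequence": raw,
                "charge": int(z),
                "length": props.length,
                "mass": props.mass,
                "mz": props.mz,
                "gravy": props.gravy,
                "pi": props.pi,
                "mass_length_ratio": props.mass_length_ratio,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sequence", "charge", "length", "mass", "mz",
            "gravy", "pi", "mass_length_ratio",
        ],
    )
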