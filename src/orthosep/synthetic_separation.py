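"""Two-platform synthetic peptide identification tables.

Real identification exports from the instruments are not publicly
deposited, so every downstream analysis is exercised on simulated
tables that reproduce the statistical structure the analysis assumes:

* RPLC retention time increases with hydrophobicity (linear in GRAVY
  plus Gaussian noise);
* CZE migration time follows an Offord-type charge-to-size mobility law
  (mobility proportional to z / mass^(2/3); time inversely proportional
  to mobility, plus a small pressure-assist offset);
* DTIMS drift time follows a per-charge power law of m/z (exponent
  ~0.5, the usual collision-cross-section scaling);
* platform detection is biased: reversed-phase favours longer, heavier,
  more hydrophobic peptides, while electrophoresis favours polar and
  basic ones. Detection is Bernoulli with a logistic probability in the
  centred descriptors.

Identification score and spectrum purity index are drawn independently
of the coordinates, straddling the acceptance thresholds so the quality
filter removes a nontrivial fraction of rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .peptide_props import PeptideSequence, compute_properties, parse_sequence
from .scales import DEFAULT_SCALES, ResidueScales

#: Average residue frequencies of a generic proteome (UniProt-like),
#: renormalized to sum to 1.
DEFAULT_RESIDUE_FREQUENCIES: dict[str, float] = {
    "A": 0.0826, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0137,
    "Q": 0.0393, "E": 0.0672, "G": 0.0708, "H": 0.0227, "I": 0.0591,
    "L": 0.0970, "K": 0.0580, "M": 0.0241, "F": 0.0386, "P": 0.0475,
    "S": 0.0665, "T": 0.0536, "W": 0.0110, "Y": 0.0292, "V": 0.0686,
}


@dataclass(frozen=True)
class LogisticBias:
    """Logistic detection model: logit = intercept + sum(coef * (x - center))."""

    intercept: float = 0.0
    length: float = 0.0
    mass: float = 0.0
    gravy: float = 0.0
    pi: float = 0.0
    length_center: float = 15.0
    mass_center: float = 1600.0
    gravy_center: float = -0.4
    pi_center: float = 7.0

    def probability(self, length: float, mass: float, gravy: float, pi: float) -> float:
        logit = (
            self.intercept
            + self.length * (length - self.length_center)
            + self.mass * (mass - self.mass_center)
            + self.gravy * (gravy - self.gravy_center)
            + self.pi * (pi - self.pi_center)
        )
        return 1.0 / (1.0 + np.exp(-logit))


# Default bias strengths: reversed-phase retains long hydrophobic
# peptides; electrophoresis detects polar/basic ones preferentially.
DEFAULT_RPLC_BIAS = LogisticBias(length=0.10, gravy=0.8, pi=-0.35)
DEFAULT_CZE_BIAS = LogisticBias(length=-0.10, gravy=-0.8, pi=0.35)


@dataclass
class SyntheticConfig:
    """Every knob of the simulator; defaults give a ~60 min gradient run."""

    n_proteins: int = 30
    protein_length_mean: float = 450.0
    protein_length_sd: float = 120.0
    protein_length_min: int = 50
    residue_frequencies: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RESIDUE_FREQUENCIES)
    )
    max_missed_cleavages: int = 2
    peptide_length_range: tuple[int, int] = (6, 50)

    # rt = rt_intercept + rt_slope * GRAVY + N(0, rt_noise_sd), minutes
    rt_intercept: float = 25.0
    rt_slope: float = 8.0
    rt_noise_sd: float = 1.0

    # mobility mu = mobility_constant * z / mass^(2/3);
    # mt = mt_time_scale / mu + mt_offset + N(0, mt_noise_sd), minutes
    mobility_constant: float = 1.0
    mt_time_scale: float = 0.45
    mt_offset: float = 1.0  # small pressure-assist contribution
    mt_noise_sd: float = 0.3

    # dt = dt_a[z] * (m/z)^dt_b[z] + N(0, dt_noise_sd), milliseconds
    dt_a: dict[int, float] = field(
        default_factory=lambda: {2: 1.00, 3: 0.92, 4: 0.86, 5: 0.82, 6: 0.79, 7: 0.77}
    )
    dt_b: dict[int, float] = field(
        default_factory=lambda: {z: 0.5 for z in range(2, 8)}
    )
    dt_noise_sd: float = 0.3

    rplc_bias: LogisticBias = field(default_factory=lambda: DEFAULT_RPLC_BIAS)
    cze_bias: LogisticBias = field(default_factory=lambda: DEFAULT_CZE_BIAS)

    # variable-modification rates per eligible residue
    met_oxidation_rate: float = 0.10
    asn_deamidation_rate: float = 0.05

    # identification score ~ U(0, 15); SPI ~ U(0, 100): both straddle
    # the acceptance thresholds (score > 5, SPI > 50)
    score_range: tuple[float, float] = (0.0, 15.0)
    spi_range: tuple[float, float] = (0.0, 100.0)

    charge_range: tuple[int, int] = (2, 7)
    seed: int = 0

    def validate(self) -> None:
        freq_sum = sum(self.residue_frequencies.values())
        if abs(freq_sum - 1.0) > 1e-9:
            raise ValueError(f"residue frequencies sum to {freq_sum}, expected 1")
        for name in ("rt_noise_sd", "mt_noise_sd", "dt_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if self.protein_length_mean <= 0:
            raise ValueError("protein_length_mean must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def generate_proteins(cfg: SyntheticConfig, rng: np.random.Generator | None = None):
    """Random protein pool: i.i.d. residues, Gaussian lengths (floored).

    Returns a list of (accession, sequence) tuples; deterministic for a
    fixed config seed.
    """
    cfg.validate()
    rng = rng or np.random.default_rng(cfg.seed)
    letters = sorted(cfg.residue_frequencies)
    probs = np.array([cfg.residue_frequencies[a] for a in letters])
    probs = probs / probs.sum()
    pool = []
    for i in range(cfg.n_proteins):
        length = max(
            cfg.protein_length_min,
            int(round(rng.normal(cfg.protein_length_mean, cfg.protein_length_sd))),
        )
        seq = "".join(rng.choice(letters, size=length, p=probs))
        pool.append((f"SYN{i:04d}", seq))
    return pool


def write_fasta(pool, path) -> None:
    """Write the protein pool as FASTA via Biopython."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=acc, description="synthetic protein")
        for acc, seq in pool
    ]
    seqio_write(records, str(path), "fasta")


def tryptic_digest(protein: str, max_missed: int = 2) -> list[str]:
    """All tryptic fragments with 0..max_missed internal missed cleavages.

    Cleavage occurs after K or R except when the next residue is P. The
    zero-missed-cleavage fragments concatenate back to the input.
    """
    if not protein:
        raise ValueError("empty protein sequence")
    sites = [0]
    for i in range(len(protein) - 1):
        if protein[i] in "KR" and protein[i + 1] != "P":
            sites.append(i + 1)
    sites.append(len(protein))
    peptides = []
    for a in range(len(sites) - 1):
        for b in range(a + 1, min(a + 2 + max_missed, len(sites))):
            peptides.append(protein[sites[a]:sites[b]])
    return peptides


def assign_charge(peptide: str, charge_range: tuple[int, int] = (2, 7)) -> int:
    """Charge model: one proton on the N-terminus plus one per basic residue
    (K, R, H), clipped into the instrument's charge range."""
    z = 1 + sum(peptide.count(r) for r in "KRH")
    return int(np.clip(z, charge_range[0], charge_range[1]))


def predict_coordinates(
    mass: float, gravy: float, z: int, cfg: SyntheticConfig, rng: np.random.Generator
) -> tuple[float, float, float]:
    """(rt, mt, dt) for one peptide under the configured separation models."""
    mobility = cfg.mobility_constant * z / mass ** (2.0 / 3.0)
    if mobility <= 0:
        raise ValueError(f"non-positive mobility {mobility} (z={z}, mass={mass})")
    rt = cfg.rt_intercept + cfg.rt_slope * gravy + rng.normal(0.0, cfg.rt_noise_sd)
    mt = cfg.mt_time_scale / mobility + cfg.mt_offset + rng.normal(0.0, cfg.mt_noise_sd)
    mz = (mass + z * 1.007276) / z
    a = cfg.dt_a.get(z, list(cfg.dt_a.values())[-1])
    b = cfg.dt_b.get(z, 0.5)
    dt = a * mz**b + rng.normal(0.0, cfg.dt_noise_sd)
    eps = 1e-6
    return max(rt, eps), max(mt, eps), max(dt, eps)


def _apply_modifications(
    peptide: str, cfg: SyntheticConfig, rng: np.random.Generator
) -> str:
    out = []
    for ch in peptide:
        if ch == "M" and rng.random() < cfg.met_oxidation_rate:
            out.append("m")
        elif ch == "N" and rng.random() < cfg.asn_deamidation_rate:
            out.append("n")
        else:
            out.append(ch)
    return "".join(out)


def build_peptide_catalog(
    cfg: SyntheticConfig,
    rng: np.random.Generator | None = None,
    scales: ResidueScales = DEFAULT_SCALES,
) -> pd.DataFrame:
    """Digest a generated protein pool into a unique-peptide catalog.

    One row per distinct (modified sequence, protein-of-first-origin)
    pair with charge, descriptors and noiseless/noisy coordinates. The
    shared TSV columns are sequence, charge, mz, rt, mt, dt, protein,
    plus the descriptors used by the detection model.
    """
    cfg.validate()
    rng = rng or np.random.default_rng(cfg.seed)
    pool = generate_proteins(cfg, rng)
    lo, hi = cfg.peptide_length_range
    rows = []
    seen: set[str] = set()
    for acc, protein in pool:
        for pep in tryptic_digest(protein, cfg.max_missed_cleavages):
            if not lo <= len(pep) <= hi or pep in seen:
                continue
            seen.add(pep)
            modified = _apply_modifications(pep, cfg, rng)
            parsed = parse_sequence(modified, scales)
            z = assign_charge(pep, cfg.charge_range)
            props = compute_properties(parsed, z, scales)
            rt, mt, dt = predict_coordinates(props.mass, props.gravy, z, cfg, rng)
            rows.append(
                {
                    "sequence": modified,
                    "charge": z,
                    "mz": props.mz,
                    "rt": rt,
                    "mt": mt,
                    "dt": dt,
                    "protein": acc,
                    "length": props.length,
                    "mass": props.mass,
                    "gravy": props.gravy,
                    "pi": props.pi,
                    "mass_length_ratio": props.mass_length_ratio,
                }
            )
    return pd.DataFrame(rows)


def sample_platform_detection(
    catalog: pd.DataFrame,
    cfg: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bernoulli platform detection over the catalog.

    Returns (rplc_table, cze_table) in the shared identification-record
    schema; detection on the two platforms is independent given the
    descriptors. Score and SPI are drawn per detected record.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    tables = []
    for platform, bias in (("RPLC", cfg.rplc_bias), ("CZE", cfg.cze_bias)):
        if catalog.empty:
            tables.append(_empty_table(platform))
            continue
        p = np.array(
            [
                bias.probability(r.length, r.mass, r.gravy, r.pi)
                for r in catalog.itertuples()
            ]
        )
        detected = catalog[rng.random(len(catalog)) < p].copy()
        detected["platform"] = platform
        detected["score"] = rng.uniform(*cfg.score_range, size=len(detected))
        detected["spi"] = rng.uniform(*cfg.spi_range, size=len(detected))
        tables.append(detected.reset_index(drop=True))
    return tables[0], tables[1]


def _empty_table(platform: str) -> pd.DataFrame:
    cols = [
        "sequence", "charge", "mz", "rt", "mt", "dt", "protein",
        "length", "mass", "gravy", "pi", "mass_length_ratio",
        "platform", "score", "spi",
    ]
    return pd.DataFrame(columns=cols)


def simulate(cfg: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full simulation: proteins -> digest -> coordinates -> two platforms."""
    rng = np.random.default_rng(cfg.seed)
    catalog = build_peptide_catalog(cfg, rng)
    return sample_platform_detection(catalog, cfg, rng)
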