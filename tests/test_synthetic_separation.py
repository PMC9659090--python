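"""Simulator: digestion, coordinate models, platform-detection bias."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from orthosep.peptide_props import compute_properties, parse_sequence
from orthosep.synthetic_separation import (
    SyntheticConfig,
    assign_charge,
    build_peptide_catalog,
    generate_proteins,
    predict_coordinates,
    sample_platform_detection,
    simulate,
    tryptic_digest,
    write_fasta,
)


def brute_force_digest(protein: str, max_missed: int) -> set[str]:
    """Independent oracle: test every substring against the cleavage rule."""
    boundaries = {0, len(protein)}
    for i in range(len(protein) - 1):
        if protein[i] in "KR" and protein[i + 1] != "P":
            boundaries.add(i + 1)
    out = set()
    for start in sorted(boundaries):
        for end in sorted(boundaries):
            if end <= start:
                continue
            internal = sum(1 for b in boundaries if start < b < end)
            if internal <= max_missed:
                out.add(protein[start:end])
    return out


class TestDigest:
    def test_no_cleavage_before_proline(self):
        assert set(tryptic_digest("AKRP", max_missed=0)) == {"AK", "RP"}

    def test_consecutive_cleavage_sites(self):
        assert tryptic_digest("KKK", max_missed=0) == ["K", "K", "K"]

    def test_zero_missed_fragments_concatenate_to_input(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            protein = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
            assert "".join(tryptic_digest(protein, 0)) == protein

    @pytest.mark.parametrize("max_missed", [0, 1, 2, 3])
    def test_matches_substring_enumeration_oracle(self, max_missed):
        rng = np.random.default_rng(7)
        for _ in range(10):
            protein = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=50))
            assert set(tryptic_digest(protein, max_missed)) == brute_force_digest(
                protein, max_missed
            )

    def test_matches_pyteomics_cleave(self):
        parser = pytest.importorskip("pyteomics.parser")
        rng = np.random.default_rng(23)
        for _ in range(10):
            protein = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=80))
            ours = set(tryptic_digest(protein, 2))
            theirs = parser.cleave(protein, parser.expasy_rules["trypsin"], 2)
            assert ours == set(theirs)

    def test_empty_protein_rejected(self):
        with pytest.raises(ValueError):
            tryptic_digest("", 2)


class TestProteinPool:
    def test_empty_pool(self):
        assert generate_proteins(SyntheticConfig(n_proteins=0)) == []

    def test_deterministic_under_seed(self, tmp_path):
        cfg = SyntheticConfig(seed=17, n_proteins=5)
        a, b = tmp_path / "a.fasta", tmp_path / "b.fasta"
        write_fasta(generate_proteins(cfg), a)
        write_fasta(generate_proteins(cfg), b)
        assert a.read_bytes() == b.read_bytes()

    def test_degenerate_frequency_vector(self):
        freqs = {r: 0.0 for r in "ACDEFGHILMNPQRSTVWY"}
        freqs["K"] = 1.0
        cfg = SyntheticConfig(n_proteins=3, residue_frequencies=freqs, seed=1)
        for _, seq in generate_proteins(cfg):
            assert set(seq) == {"K"}

    def test_invalid_length_distribution_rejected(self):
        with pytest.raises(ValueError):
            generate_proteins(SyntheticConfig(protein_length_mean=-10.0))

    def test_frequencies_must_sum_to_one(self):
        freqs = dict(SyntheticConfig().residue_frequencies)
        freqs["A"] += 0.01
        with pytest.raises(ValueError, match="frequencies"):
            SyntheticConfig(residue_frequencies=freqs).validate()


class TestCoordinateModels:
    def _props(self, seq, z):
        return compute_properties(parse_sequence(seq), z)

    def test_zero_noise_equal_mass_and_charge_give_equal_mt(self):
        cfg = SyntheticConfig(rt_noise_sd=0, mt_noise_sd=0, dt_noise_sd=0)
        rng = np.random.default_rng(0)
        # Leu/Ile are isobaric: identical mass, same charge
        a = self._props("LLLKK", 2)
        b = self._props("IIIKK", 2)
        _, mt_a, _ = predict_coordinates(a.mass, a.gravy, 2, cfg, rng)
        _, mt_b, _ = predict_coordinates(b.mass, b.gravy, 2, cfg, rng)
        assert mt_a == pytest.approx(mt_b)

    def test_rt_tracks_gravy_without_noise(self):
        cfg = SyntheticConfig(rt_noise_sd=0, mt_noise_sd=0, dt_noise_sd=0)
        rng = np.random.default_rng(0)
        gravies = np.linspace(-3, 3, 15)
        rts = [predict_coordinates(1500.0, g, 2, cfg, rng)[0] for g in gravies]
        rho = stats.spearmanr(gravies, rts).statistic
        assert rho == pytest.approx(1.0)

    def test_higher_charge_migrates_earlier_at_fixed_mass(self):
        cfg = SyntheticConfig(rt_noise_sd=0, mt_noise_sd=0, dt_noise_sd=0)
        rng = np.random.default_rng(0)
        mts = [predict_coordinates(2000.0, 0.0, z, cfg, rng)[1] for z in range(2, 8)]
        assert mts == sorted(mts, reverse=True)

    def test_charge_model_counts_basic_residues(self):
        assert assign_charge("GGGGGG") == 2  # N-terminus only, clipped up to 2
        assert assign_charge("GGKGGR") == 3  # 1 + 2 basics
        assert assign_charge("KRKRKRKRKR") == 7  # clipped at 7


class TestPlatformDetection:
    def test_zero_coefficients_give_half_probability(self):
        from orthosep.synthetic_separation import LogisticBias

        bias = LogisticBias()
        assert bias.probability(30, 3000.0, 2.0, 11.0) == pytest.approx(0.5)

    def test_zero_peptides_in_gives_empty_tables(self):
        cfg = SyntheticConfig(n_proteins=0, seed=1)
        empty = build_peptide_catalog(cfg)
        rplc, cze = sample_platform_detection(empty, cfg)
        assert rplc.empty and cze.empty

    def test_bias_defaults_recover_reported_direction(self):
        """CZE-detected peptides are more basic, RPLC-detected longer/heavier."""
        cfg = SyntheticConfig(seed=42, n_proteins=60)
        catalog = build_peptide_catalog(cfg)
        assert len(catalog) >= 2000
        catalog = catalog.iloc[:2000]
        rplc, cze = sample_platform_detection(catalog, cfg)
        p = stats.mannwhitneyu(cze["pi"], rplc["pi"], alternative="greater").pvalue
        assert p <= 0.05
        assert rplc["length"].mean() > cze["length"].mean()
        assert rplc["mass"].mean() > cze["mass"].mean()

    def test_simulation_deterministic_under_seed(self):
        cfg = SyntheticConfig(seed=5, n_proteins=8)
        r1, c1 = simulate(cfg)
        r2, c2 = simulate(SyntheticConfig(seed=5, n_proteins=8))
        pd.testing.assert_frame_equal(r1, r2)
        pd.testing.assert_frame_equal(c1, c2)

    def test_zero_bias_zero_noise_platforms_detect_same_population(self):
        """With no bias the two platforms sample the same peptide set in
        expectation; uniqueness is symmetric noise, not structure."""
        from orthosep.synthetic_separation import LogisticBias

        always = LogisticBias(intercept=50.0)  # p ~ 1 for every peptide
        cfg = SyntheticConfig(
            seed=9, n_proteins=6, rplc_bias=always, cze_bias=always,
            rt_noise_sd=0.0, mt_noise_sd=0.0, dt_noise_sd=0.0,
        )
        rplc, cze = simulate(cfg)
        assert set(rplc["sequence"]) == set(cze["sequence"])
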