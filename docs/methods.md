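# Methods

`orthosep` quantifies how much extra separation power a second (or third)
dimension adds to a peptide separation — reversed-phase liquid
chromatography (RPLC, retention time in minutes), capillary zone
electrophoresis (CZE, migration time in minutes) and drift-tube ion
mobility (DTIMS, drift time in milliseconds) — and how complementary two
platforms are in the peptide populations they identify.

## Orthogonality metrics

**Surface-coverage (bin-counting) method.** Both coordinates are min-max
normalized to [0, 1]; the unit square is divided into a `side × side`
grid with `side = ⌈√N⌉` so the number of bins tracks the number of data
points. Bins are half-open on [0, 1) with the final bin closed, so a
point at the axis maximum is counted exactly once. The orthogonality
factor is

    factor = (occupied − side) / (0.63 · side²)

The `side` term removes the bins a perfectly correlated (diagonal)
dataset would occupy, so perfectly correlated dimensions score exactly 0.
The 0.63 constant is the surface coverage regarded as the practical
optimum for an orthogonal pair of separations (full coverage being
unattainable), so an ideally orthogonal system scores ≈ 1. For N points
i.i.d. uniform on the unit square the expected occupied-bin count is
`B(1 − (1 − 1/B)^N)` with `B = side²`; a Monte-Carlo test checks the mean
factor against this closed form, which is what pins down the
normalization.

The factor is invariant to affine rescaling of either axis (min-max
normalization absorbs it) but **not** to general monotone rescaling,
which redistributes points across bins. Duplicate coordinate pairs are
kept; when pooled replicates are analyzed they are pooled before
normalization.

**Regression-deviation method.** The second coordinate is regressed on
the first by ordinary least squares *without* normalization. Residuals
are expressed as a percentage of the observed y-range. To prevent a few
stragglers from inflating the band, the most extreme 5 % of residuals
(2.5 % per tail, count floored) are discarded *after* the fit — the fit
itself uses all points. The surviving extreme residuals give the band
bounds (negative, positive); the occupied space is their total width in
percent and the factor is that width divided by 100. Collinear data
score 0; both the trim fraction and the bounds are exposed so a
pre-measured pair of bounds can be converted directly
(`factor_from_deviation_bounds`).

The two metrics are kept deliberately independent: agreement between
them is itself evidence that an orthogonality estimate is not an
artifact of one method's assumptions.

## Peak capacity

Peak capacity of a one-dimensional window is
`1 + (MT_L − MT_F) / (ΣW4σ/n)` where `MT_F`/`MT_L` are the apex times
of the first and last peak and `W4σ` is the peak width at 13.4 % of
maximum height. Widths measured as FWHM are converted assuming Gaussian
peaks: `W4σ = FWHM · 4/(2√(2 ln 2)) ≈ 1.69864 · FWHM`. Using the 4σ
width rather than FWHM avoids overestimating capacity. Capacity is
invariant to time shifts and to uniform time dilation (window and widths
scale together).

## Co-migration / co-isolation and drift-time resolution

Two identifications risk producing a chimeric fragmentation spectrum if
they co-migrate (|Δmt| ≤ 0.1 min) **and** are co-isolated
(|Δm/z| ≤ 0.001 Th); both comparisons are inclusive. Groups are the
connected components of the graph joining all such pairs (transitive
closure) — a triplet sharing one migration time and precursor m/z is one
group, not three independent pairs, though the pairwise count is also
reported. A member pair counts as drift-resolved when |Δdt| ≥ 0.5 ms;
the default borrows the drift-alignment window used during MS/MS
extraction and is configurable, since no universal resolution criterion
exists. Distinct resolvable species per group are single-linkage
components on the drift axis. Pairs with a missing drift time are
reported unassessable, never resolved.

## Peptide descriptors

Length, monoisotopic mass (residue masses + water + modification
deltas; carbamidomethyl-Cys +57.021464 Da applied as a fixed
modification by default), precursor m/z `(mass + z·1.007276)/z`, GRAVY
(mean Kyte–Doolittle hydropathy; modified residues contribute the parent
residue's value), mass/length ratio, and pI. Sequences use the
search-engine export convention of lowercase letters for variable
modifications: `m` oxidized Met (+15.994915), `n`/`q` deamidated
Asn/Gln (+0.984016), `k` carbamidomethyl-propionyl Lys (+113.047679,
biotinylation workflows). Deamidated Asn/Gln gain a carboxylate and are
titrated as Asp/Glu.

The pI is the root of the Henderson–Hasselbalch net-charge function
(N-terminus, C-terminus, and the C/D/E/H/K/R/Y side chains), found by
bisection on pH ∈ [0, 14] to |net charge| < 1e-4 and bracket < 1e-6 pH
units. Net charge is monotone non-increasing in pH, so the root is
unique. The pKa set defaults to the EMBOSS values and is configurable:
absolute pI values depend on the convention, and the convention used to
produce any given exported table is generally unknown, so comparisons
across tables should use one consistent set.

## Synthetic two-platform tables

Real vendor exports for this kind of study are rarely deposited, so the
package ships a simulator that reproduces the *statistical structure*
the analysis assumes, not accurate physics:

- **Protein pool**: i.i.d. residues at average proteome frequencies,
  Gaussian lengths (mean 450, sd 120, floor 50 residues).
- **Digestion**: tryptic (cleave after K/R except before P), up to 2
  missed cleavages, peptides kept at 6–50 residues.
- **Charge**: 1 (N-terminus) + count of K/R/H, clipped to the
  instrument range 2–7.
- **Retention time**: `25 + 8·GRAVY + N(0, 1)` min — hydrophobicity
  drives reversed-phase retention.
- **Migration time**: Offord-type charge-to-size mobility
  `μ = z/mass^(2/3)`; `mt = 0.45/μ + 1 + N(0, 0.3)` min. The constant
  1 min offset emulates the small pressure-assist contribution of a
  low-pressure ramp during the run.
- **Drift time**: `a_z·(m/z)^0.5 + N(0, 0.3)` ms with per-charge
  prefactors 1.00 … 0.77 for z = 2 … 7 — the usual collision-cross-
  section power-law scaling. Because mt and dt both derive from
  mass and charge they are strongly correlated, which is exactly the
  structure the orthogonality ordering test exploits.
- **Platform detection**: independent Bernoulli draws with logistic
  probability in the centred descriptors. Defaults: RPLC logit
  `+0.10·(length−15) + 0.8·(GRAVY+0.4) − 0.35·(pI−7)` and the mirror
  image for CZE, so reversed-phase preferentially detects longer,
  heavier, more hydrophobic peptides and electrophoresis more polar,
  basic ones. All-zero coefficients give exactly p = 0.5.
- **Quality scores**: identification score ~ U(0, 15) and spectrum
  purity index ~ U(0, 100), independent of the coordinates, so the
  acceptance filter (score > 5 AND SPI > 50 %, both strict) removes a
  nontrivial, structure-free fraction.

What the simulator does **not** emulate: real retention/mobility
calibration, intensity-dependent identification, shared-peptide protein
inference, modification-dependent coordinate shifts, or inter-replicate
drift. Passing tests therefore demonstrate that the analysis machinery
is correct and directionally faithful, not that it reproduces any
particular instrument's numbers.

## Numerical choices and degenerate inputs

- Min-max normalization rejects a zero-range axis by name.
- The bin-method requires N ≥ 3; the regression method additionally
  rejects constant x. A constant-y input yields zero residuals and
  factor 0.
- Constant descriptor columns are excluded from PCA (they cannot be
  standardized) with a logged warning; PCA runs on the correlation
  structure because the descriptors carry incommensurate units.
- Mann–Whitney tests use exact enumeration for group sizes ≤ 20
  (falling back to the asymptotic form if ties prevent it) and the
  tie-corrected normal approximation otherwise.
- Tolerance comparisons in co-clustering are inclusive; the union-find
  prefilters candidate pairs by sorting on m/z.
- All simulator randomness flows from one `numpy` Generator seeded from
  the config, making every run byte-reproducible.

## Problem sizes

The test suite and the pipeline demo run on simulated pools of 6–60
proteins (roughly 400–4000 catalog peptides), Monte-Carlo calibration at
N ∈ {100, 1000} with 200 replicates, and brute-force oracle comparisons
on ≤ 100-element inputs — sizes chosen so the whole suite completes in
well under a minute while still exercising every code path at realistic
peptide counts.

## Known limitations

- Absolute pI values are convention-dependent (pKa set); only
  within-convention comparisons are meaningful.
- The bin-method factor is noisy at small N (side = ⌈√N⌉ makes the grid
  coarse); pooling replicates before binning is recommended.
- The regression method measures deviation vertically as a fraction of
  the y-range, so swapping the axes changes the result; callers should
  keep the convention of regressing the second dimension on the first.
- The simulator's platform-unique fractions are driven entirely by the
  logistic bias defaults and Bernoulli noise; they are not calibrated to
  any particular instrument pair.
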