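# Methods

## Motif-architecture model

A class III phosphodiesterase signature is modelled as seven ordered elements
over the amino-acid alphabet — `D`, `H`, `GD`, one of `GNHD`/`GNHE`/`GNCD`,
`H`, `GH`, `H` (12 residues total) — separated by six spacers, where a spacer
counts residues *strictly between* consecutive elements. Coordinates are
0-based. `D(X)H` and `GH(X)H` pin spacers 1→2 and 6→7 to exactly one
residue; the four inner spacers vary and carry the subclass signal.

`scan_architecture` enumerates candidate occurrences of each element and runs
a dynamic program over them: for each occurrence of element *i* it tabulates
the minimal achievable penalty of the suffix *i*..7, where the penalty of a
placement is the summed distance of its four variable spacers to the
signature's reference intervals (0 inside; 1 per residue outside; inner
spacers additionally capped at `max_spacer`, default 150). All optimal paths
are then reconstructed, so the scanner returns *every* minimal-penalty
placement, sorted by penalty and then lexicographically smallest position
vector. On short sequences this provably equals exhaustive enumeration, and
the test suite checks that equivalence on 500 seeded random/planted cases
plus a derandomized property test. Ambiguity codes (B, Z, J, U, O, X) are
accepted in input but never match a motif position; other letters are
rejected with the offending position named.

Two signatures are used in practice: the *subclass-A reference* signature
(variable-spacer bounds 37–38, 28–32, 68–70, 35–37) and a *permissive union*
signature whose bounds are the union of all subclass intervals in the active
rule table. The classify pipeline scans with the union signature so that a
conformant member of any subclass is a zero-penalty match, while a spurious
placement still needs a full in-interval seven-element architecture.

## Subclass rules

Classification evidence is (i) the motif-IV variant — `GNCD` is unique to
subclass IIIC, `GNHD`/`GNHE` are shared by IIIA/IIIB — (ii) the four variable
spacers, and (iii) sequence length. The score of a label is the summed
distance-to-interval of the spacers plus `length_weight` (default 0.1 per
residue) times the distance of the length to the label's length interval;
the lowest-scoring admissible label wins, with ties broken IIIA < IIIB <
IIIC, and scores above `threshold` (default 10 penalty units) yield
`unclassified` — the threshold makes the classifier total, since real
collections contain sequences matching none of the three patterns well.

Only the IIIA spacer intervals are established reference values. The IIIB
and IIIC defaults are **calibration artifacts of this package**: intervals
(16–18, 29–31, 61–63, 20–22) and (13–15, 29–31, 27–29, 11–13) respectively,
with length intervals ±15% around the 285/243/183 aa subclass averages.
They were chosen under three constraints: componentwise monotone deletions
(A ≥ B ≥ C in every spacer), totals consistent with the subclass size
averages, and *deletion patterns that differ in direction between IIIB and
IIIC* (IIIB shortens mainly the II–III and V–VI spacers, IIIC mainly the
IV–V spacer). The last constraint matters for the tree stage: if the three
subclass centroids are collinear in spacer space (which happens when the
deletions are proportional), the exact additive representation of the
distances is a path and the *middle* subclass can never be monophyletic
under neighbor joining — an early draft of the defaults hit exactly this
geometry, confirmed independently with scikit-bio's NJ. Users with real
labelled sequences should replace the defaults via `calibrate_rules`
(per-label min/max intervals, optional margin) or a rule file; calibration
refuses labels with fewer than two profiles and contradictory motif-IV
evidence.

## Synthetic sequences

`simulate_sequences` plants exactly one architecture per record: spacers
drawn uniformly from the subclass intervals, the motif-IV variant per
subclass (IIIA draws GNHD or GNHE; IIIB GNHD; IIIC GNCD), target length
uniform in ±5% of the subclass average, and flanks split randomly.
Background residues are i.i.d. from a configurable distribution, by default
uniform over the 20 amino acids with D, H and G down-weighted ×0.5 — the
down-weighting keeps spurious architectures rare without touching the
planted spacing statistics. With decoy suppression on (default), the
background is resampled (up to 200 tries) until the planted placement is the
scanner's *unique* zero-penalty match under the union signature, so truth
tables re-validate exactly.

What this emulates — and does not: the generator reproduces the spacing
architecture, subclass size ranges and motif-IV variants of real class III
PDEs, but real proteins have compositional biases, homologous flanking
domains, and partially degenerate motifs that i.i.d. backgrounds lack.
Passing round trips therefore validate the scanner/classifier logic, not its
sensitivity on remote homologs.

## Assay models and fits

All fits are unweighted nonlinear least squares via
`scipy.optimize.least_squares`, tolerances 1e-10 or tighter, no outlier
rejection.

**Specific activity** converts an endpoint A405 to μmol p-nitrophenol
min⁻¹ mg⁻¹ by Beer–Lambert (ε = 18,450 M⁻¹cm⁻¹, path 1 cm defaults).

**Michaelis–Menten.** Km and Vmax are log-transformed to enforce positivity
and fit unconstrained (Levenberg–Marquardt); standard errors come from the
Gauss–Newton covariance in log space mapped back by the delta method.
Default initial values Km = median(S), Vmax = max(v). Substrate
concentrations are carried in mM; molarity enters only in the efficiency
`kcat/Km`. The default molar mass is **29.5 kDa**: the reported
kcat/Vmax pairs for both substrates imply exactly this value
(102450/3473 = 60.21/2.041 = 29.50), while the His-tagged protein's stated
theoretical mass is ~29.3 kDa; the parameter is configurable everywhere it
appears and the discrepancy is deliberate, favouring internal consistency of
the derived constants.

**Hill binding.** The fractional quench `(F₀−F)/F₀` is fit to
`Y = Bmax·Xʰ/(Kdʰ+Xʰ)` with bounds Kd ∈ (1e-4, 100] mM, h ∈ (0.05, 4],
Bmax ∈ (0, 1.2]; baseline offset is fixed at 0 and `Y(0) = 0` exactly. Bmax
is free by default because the quencher-accessible fraction of the
fluorescence need not be 1. However, on a titration that stops well short of
saturation (the standard 0–4.5 mM Mn²⁺ design reaches only ≈56% of Bmax at
h = 0.5), Bmax and Kd are nearly collinear: the Cramér–Rao bound at the
reference parameters (Kd 2.67 mM, h 0.5, σ = 0.03 additive) gives
sd(Kd) ≈ 6 mM — the free-Bmax Kd is essentially unidentified, and reported
sub-percent precisions on Kd from such designs are only attainable with Bmax
constrained. `fit_binding(..., fix_bmax=1.0)` provides that constraint
(complete quench at saturation) and is what the parameter-recovery
experiments use; with it, the 200-replicate mean recovers Kd and h to well
within a percent of truth.

**Thermal melts.** The CD-at-222-nm profile is fit to a native plateau
followed by one-phase exponential decay,
`Y(T) = Y0` for `T < X0`, `Y(T) = P + (Y0−P)·e^{−K(T−X0)}` for `T ≥ X0`,
with X0 bounded to the observed temperature range. The melting temperature
is where the fitted curve crosses the midpoint of the two extrapolated
baselines, which for this model is the closed form `Tm = X0 + ln 2/K`
(verified against a numerical root find to 1e-9). Flat profiles (no
separation between the baselines) return `converged=False` with Tm = NaN
rather than raising. A symmetric two-baseline logistic is available via
`fit_melt(..., model="logistic")` as a sensitivity check; temperatures are
°C throughout.

**Noise models.** `simulate_assay` perturbs the exact model curve with
proportional (`y·(1+σε)`) or additive (`y+σε`) Gaussian noise; replicate *r*
(1-based) uses an RNG seeded `seed + r`, so runs are reproducible and
σ = 0 reproduces the model exactly. Reference parameter defaults are the
characterized enzyme's values: Km 10.21 mM / Vmax 3473 μmol min⁻¹ mg⁻¹ (bis(pNPP),
5% proportional noise in recovery experiments, 12 concentrations spanning
0.5–40 mM), Kd 2.67 mM / h 0.5 / Bmax 1 (Mn²⁺ quench, 3% additive noise,
8 concentrations 0–4.5 mM), and a melt with onset 50 °C parameterized to a
59.92 °C midpoint on a 20–80 °C, 1 °C grid.

## Feature-space tree stage

Pairwise distances between spacer profiles are Euclidean over the four
variable spacers plus `length_weight·|Δlength|`. Neighbor joining is the
classic Saitou–Nei agglomeration (Q-criterion, standard limb lengths,
distance reduction), deterministic with ties broken on the smallest index
pair; negative limb estimates are clamped to 0; trees are scikit-bio
`TreeNode`s with a trifurcating root (unrooted convention) and serialize to
newick. `cluster_purity` is the fraction of subclasses separated exactly by
some edge of the tree (singleton and whole-set groups count as trivially
monophyletic). This stage deliberately replaces alignment-based phylogenies:
the claim it can support is the weaker, testable one that *spacing
architecture alone* separates the subclasses at desk scale — on the default
60-sequence fixture the purity is 1.0.

## Problem sizes and numerical choices

Recovery experiments use 200 replicates per scenario (the means are stable
to ≪1% across seeds at this size); the scanner/oracle equivalence suite uses
500 cases of ≤120 aa against a compact test signature; NJ correctness is
checked on exactly additive matrices up to 8 taxa, with an exhaustive
least-squares topology search as oracle up to 6 taxa (105 topologies).
Tie-breaks everywhere are deterministic (penalty then position vector in the
scanner; label order in classification; index pair in NJ), so every pipeline
stage is a pure function of its inputs and seeds.

## Known limitations

- Motif elements are exact strings; degenerate positions (beyond the three
  motif-IV variants) are not expressible in the pattern language.
- The IIIB/IIIC rule intervals are synthetic calibration values, not
  literature constants; conclusions about real sequences require
  recalibration on labelled data.
- The binding model fixes the baseline at 0 and does not model the
  concentration-dependent denaturation that can dominate fluorescence
  quenching at high metal concentrations (fits should be restricted to the
  pre-denaturation range).
- The melt model's decay-onset form has a non-smooth corner at X0; on very
  noisy profiles the X0/K split can trade off even though Tm stays stable.
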