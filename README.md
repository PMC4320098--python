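# pdekit

Tools for characterizing **class III phosphodiesterases (PDEs)** — the
bacterial metallophosphoesterases that carry the seven-motif bimetal
catalytic core `D(X)H(X)nGD(X)nGNHD(X)nH(X)nGH(X)H` — from their protein
sequences and from standard enzyme-characterization assays.

The package bundles four analyses that are usually done ad hoc:

1. **Motif-architecture scanning.** A dynamic-programming scanner locates
   every minimal-penalty placement of the seven signature elements in a
   protein sequence. A *spacer* is the number of residues strictly between
   consecutive motifs (the `(X)n` runs); the first and last spacers are fixed
   at 1 by the signature itself, and the four variable spacers are scored
   against reference intervals (penalty 0 inside, 1 per residue outside).
2. **Subclass classification.** Class III PDEs split into three subclasses:
   IIIA (≈285 aa, spacers 37–38 / 28–32 / 68–70 / 35–37), IIIB (≈243 aa) and
   IIIC (≈183 aa, recognizable by a `GNCD` fourth motif in place of
   `GNH[D/E]`). Sequences are assigned the lowest-deviation subclass, or
   `unclassified` above a configurable threshold. Rule tables can be
   calibrated from labelled sequences (`calibrate_rules`) or loaded from a
   plain-text file.
3. **Curve fits for enzyme characterization**, with explicit units:
   - specific activity from A405 via Beer–Lambert with the p-nitrophenol
     extinction coefficient ε = 18,450 M⁻¹cm⁻¹;
   - Michaelis–Menten `v = Vmax·S/(Km+S)` with log-parameter nonlinear least
     squares, then `kcat = Vmax × M` (μmol min⁻¹ mg⁻¹ × kDa ≡ min⁻¹) and
     catalytic efficiency `kcat/Km` in M⁻¹min⁻¹;
   - Hill binding `Y = Bmax·Xʰ/(Kdʰ + Xʰ)` on fractional fluorescence quench
     `(F₀−F)/F₀` (h < 1 ⇒ negative cooperativity);
   - thermal melts as a plateau followed by one-phase decay, with the melting
     temperature at the midpoint between the extrapolated baselines,
     `Tm = X0 + ln 2 / K`.
4. **Feature-space clade check.** Euclidean distances over the four variable
   spacers (plus a weighted length term), neighbor joining, and a purity
   score counting how many subclasses come out monophyletic.

A seeded synthetic-data module generates planted-architecture sequences per
subclass and noisy assay curves from any of the three models, so the whole
pipeline is testable end to end without laboratory data.

## Worked example

```python
from pdekit import AssaySimSpec, KineticDataset, derive_constants, fit_mm, simulate_assay

df = simulate_assay(AssaySimSpec("michaelis_menten", sigma=0.05,
                                 noise="proportional", seed=1))[0]
fit = fit_mm(KineticDataset(df["substrate_mM"], df["rate_umol_min_mg"]))
consts = derive_constants(fit, molar_mass=29.5)
print(f"Km = {fit.Km:.2f} mM, Vmax = {fit.Vmax:.0f} umol/min/mg")
print(f"kcat = {consts.kcat:.3e} /min, kcat/Km = {consts.efficiency:.3e} /M/min")
```

prints

```
Km = 9.89 mM, Vmax = 3461 umol/min/mg
kcat = 1.021e+05 /min, kcat/Km = 1.032e+07 /M/min
```

— one noisy 12-point bis(pNPP) saturation curve generated at Km 10.21 mM and
Vmax 3473 μmol min⁻¹ mg⁻¹, refit to within a few percent of the generating
values; kcat and kcat/Km follow from the 29.5 kDa molar mass. The
`examples/` directory holds one short script per capability
(`classify_sequences.py`, `fit_kinetics.py`, `fit_binding.py`,
`fit_melting.py`, `subclass_tree.py`).

## Command line

```sh
pdekit simulate --out-dir fixtures --seed 4          # FASTA + truth + assay CSVs
pdekit classify fixtures/sequences.fasta --out report.tsv --tree tree.nwk
pdekit fit-mm fixtures/kinetics_mm.csv --molar-mass 29.5 --out mm.json
pdekit fit-binding fixtures/binding_quench.csv --fix-bmax 1.0 --out bind.json
pdekit fit-melt fixtures/melt_cd222.csv --out melt.json
pdekit report --classify-tsv report.tsv --fit-json melt.json --out summary.json
```

Exit codes: 0 success, 2 input/configuration error, 3 fit non-convergence.

## Scope

Sequence analysis is purely motif/spacer based: no BLAST searching, multiple
sequence alignment, HMM scoring, or class I/II PDE motif handling. The tree
stage works in spacer-feature space, not on alignments, and carries no
bootstrap support. See `docs/methods.md` for models, defaults and
limitations.
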