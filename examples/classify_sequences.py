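"""Scan synthetic proteins for the seven-motif signature and call subclasses.

Generates 5 sequences per subclass with planted architectures, scans each for
the class III phosphodiesterase catalytic core D(X)H...GH(X)H, and prints the
recovered inter-motif spacers and the subclass call.  At zero noise every
sequence is recovered with its planted spacers and label.
"""

from pdekit import default_benchmark
from pdekit.pipeline import classify_records

records, truth = default_benchmark(n_per_subclass=5, seed=1)
report, profiles, labels = classify_records(records)

print(report.to_string(index=False))
agree = (report["label"].to_numpy() == truth["label"].to_numpy()).mean()
print(f"\nlabel agreement with planted truth: {agree:.0%}")
print("spacers column = residues strictly between consecutive motifs; "
      "score 0 = textbook spacing for that subclass")
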