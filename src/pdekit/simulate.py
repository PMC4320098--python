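"""Synthetic inputs for the whole pipeline.

Two generators, both seeded and reproducible to the byte:

* protein sequences with one planted seven-motif architecture at
  subclass-specific spacings over a configurable background distribution
  (defaults: uniform over the 20 amino acids with D, H and G down-weighted
  x0.5 so spurious architectures are rare), with optional decoy suppression
  that resamples the background until the planted placement is the unique
  zero-penalty match;
* assay curves (saturation kinetics, Hill binding, thermal melt) sampled
  from the generating model with proportional or additive Gaussian noise,
  one dataset per replicate, replicate r using seed ``seed + r``.

Default parameters of the assay generators are the reference estimates for
a characterized class III phosphodiesterase: Km 10.21 mM / Vmax 3473 μmol min⁻¹ mg⁻¹ for bis(pNPP), Kd 2.67 mM
with Hill slope 0.5 for Mn²⁺ binding, and a melt whose midpoint is 59.92 °C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .classify import SubclassRuleTable, default_rule_table
from .errors import InputError
from .kinetics import michaelis_menten
from .binding import hill_binding
from .melting import plateau_decay
from .motifs import (
    AMINO_ACIDS,
    SignatureDefinition,
    class_iii_signature,
    scan_architecture,
)

#: motif-IV variants planted per subclass
SUBCLASS_VARIANTS = {
    "IIIA": ("GNHD", "GNHE"),
    "IIIB": ("GNHD",),
    "IIIC": ("GNCD",),
}

#: default target-length intervals (aa), +/-5% around the subclass averages
SUBCLASS_LENGTHS = {"IIIA": (271, 299), "IIIB": (231, 255), "IIIC": (174, 192)}


def default_background() -> dict[str, float]:
    """Uniform over the 20 amino acids with D, H, G down-weighted x0.5."""
    w = {aa: 1.0 for aa in AMINO_ACIDS}
    for aa in "DHG":
        w[aa] = 0.5
    total = sum(w.values())
    return {aa: v / total for aa, v in w.items()}


def permissive_signature(
    rules: SubclassRuleTable | None = None,
) -> SignatureDefinition:
    """Signature whose reference bounds are the union of all subclass
    intervals, so any subclass-conformant placement scores penalty 0.

    This is the signature the classify pipeline scans with: it makes the
    planted architecture of every subclass a zero-penalty match while still
    requiring a full in-interval seven-element placement of any decoy.
    """
    if rules is None:
        rules = default_rule_table()
    bounds = [(1, 1)]
    for i in range(1, 5):
        intervals = [rules.rule(l).spacer_intervals[i] for l in rules.rules]
        bounds.append(
            (int(min(lo for lo, _ in intervals)), int(max(hi for _, hi in intervals)))
        )
    bounds.append((1, 1))
    return class_iii_signature(tuple(bounds))


@dataclass(frozen=True)
class SequenceSimSpec:
    """Recipe for planted-architecture sequences of one subclass."""

    label: str
    spacer_intervals: tuple[tuple[int, int], ...]  # 6, first/last (1,1)
    length_interval: tuple[int, int]  # aa
    background: dict[str, float] = field(default_factory=default_background)
    decoy_suppression: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.label not in SUBCLASS_VARIANTS:
            raise InputError(f"unknown subclass label {self.label!r}")
        if len(self.spacer_intervals) != 6:
            raise InputError("need 6 spacer intervals")
        if abs(sum(self.background.values()) - 1.0) > 1e-9:
            raise InputError("background distribution must sum to 1")
        max_span = 12 + sum(hi for _, hi in self.spacer_intervals)
        if self.length_interval[1] < max_span:
            raise InputError(
                f"length interval {self.length_interval} cannot hold a planted "
                f"span of up to {max_span} residues"
            )


def subclass_spec(label: str, seed: int = 0, **overrides) -> SequenceSimSpec:
    """Default generation spec for one subclass, drawn from the default
    rule table's intervals."""
    rule = default_rule_table().rule(label)
    intervals = tuple((int(lo), int(hi)) for lo, hi in rule.spacer_intervals)
    return SequenceSimSpec(
        label=label,
        spacer_intervals=intervals,
        length_interval=SUBCLASS_LENGTHS[label],
        seed=seed,
        **overrides,
    )


_ELEMENT_TEXT = {1: "D", 2: "H", 3: "GD", 5: "H", 6: "GH", 7: "H"}


def _assemble(spacers, variant, nter, cter, draw_bg):
    parts = [draw_bg(nter)]
    positions = []
    cursor = nter
    texts = [
        _ELEMENT_TEXT[1], _ELEMENT_TEXT[2], _ELEMENT_TEXT[3],
        variant, _ELEMENT_TEXT[5], _ELEMENT_TEXT[6], _ELEMENT_TEXT[7],
    ]
    for i, text in enumerate(texts):
        positions.append(cursor)
        parts.append(text)
        cursor += len(text)
        if i < 6:
            parts.append(draw_bg(spacers[i]))
            cursor += spacers[i]
    parts.append(draw_bg(cter))
    return "".join(parts), tuple(positions)


def simulate_sequences(
    spec: SequenceSimSpec,
    n: int,
    signature: SignatureDefinition | None = None,
    max_tries: int = 200,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Generate ``n`` FASTA records with one planted architecture each,
    plus a truth table (id, label, variant, planted positions and spacers,
    length).

    With decoy suppression on, the background is resampled until
    :func:`~pdekit.motifs.scan_architecture` (under ``signature``, default
    the permissive union signature) reports the planted placement as its
    unique zero-penalty match.
    """
    if signature is None:
        signature = permissive_signature()
    rng = np.random.default_rng(spec.seed)
    letters = np.array(list(spec.background))
    probs = np.array([spec.background[a] for a in letters])

    def draw_bg(k: int) -> str:
        if k == 0:
            return ""
        return "".join(rng.choice(letters, size=k, p=probs))

    records: list[SeqRecord] = []
    rows = []
    for idx in range(n):
        spacers = tuple(
            int(rng.integers(lo, hi + 1)) for lo, hi in spec.spacer_intervals
        )
        variant = str(rng.choice(SUBCLASS_VARIANTS[spec.label]))
        span = 12 + sum(spacers)
        lo = max(spec.length_interval[0], span)
        length = int(rng.integers(lo, spec.length_interval[1] + 1))
        flank = length - span

        for attempt in range(max_tries):
            nter = int(rng.integers(0, flank + 1))
            seq, positions = _assemble(spacers, variant, nter, flank - nter, draw_bg)
            if not spec.decoy_suppression:
                break
            matches = scan_architecture(seq, signature)
            if (
                len(matches) == 1
                and matches[0].penalty == 0
                and matches[0].positions == positions
            ):
                break
        else:
            raise InputError(
                f"could not suppress decoys in {max_tries} tries for record {idx}"
            )

        rid = f"{spec.label}_{idx:03d}"
        records.append(SeqRecord(Seq(seq), id=rid, description=""))
        rows.append(
            {
                "id": rid,
                "label": spec.label,
                "motif4_variant": variant,
                "positions": ",".join(map(str, positions)),
                "spacers": ",".join(map(str, spacers)),
                "length": length,
            }
        )
    return records, pd.DataFrame(rows)


def default_benchmark(
    n_per_subclass: int = 20, seed: int = 0
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """The standard 3-subclass fixture: ``n_per_subclass`` sequences per
    subclass, subclass seeds derived as seed, seed+1, seed+2."""
    records: list[SeqRecord] = []
    truths = []
    for offset, label in enumerate(("IIIA", "IIIB", "IIIC")):
        recs, truth = simulate_sequences(
            subclass_spec(label, seed=seed + offset), n_per_subclass
        )
        records.extend(recs)
        truths.append(truth)
    return records, pd.concat(truths, ignore_index=True)


# ---------------------------------------------------------------------------
# assay curves

ASSAY_MODELS = ("michaelis_menten", "hill_binding", "melt")

DEFAULT_ASSAY_PARAMS = {
    "michaelis_menten": {"Km": 10.21, "Vmax": 3473.0},
    "hill_binding": {"Kd": 2.67, "hill": 0.5, "Bmax": 1.0},
    "melt": {"Y0": -10.0, "P": -1.0, "X0": 50.0, "K": math.log(2.0) / 9.92},
}

DEFAULT_ASSAY_GRIDS = {
    "michaelis_menten": np.geomspace(0.5, 40.0, 12),
    "hill_binding": np.array([0.0, 0.1, 0.5, 1.0, 2.0, 3.0, 4.0, 4.5]),
    "melt": np.arange(20.0, 81.0, 1.0),
}

ASSAY_COLUMNS = {
    "michaelis_menten": ("substrate_mM", "rate_umol_min_mg"),
    "hill_binding": ("conc_mM", "quench"),
    "melt": ("temp_C", "theta222"),
}


@dataclass(frozen=True)
class AssaySimSpec:
    """Recipe for noisy replicate assay datasets from a generating model."""

    model: str
    params: dict = None
    grid: np.ndarray = None
    noise: str = "proportional"  # or "additive"
    sigma: float = 0.0
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ASSAY_MODELS:
            raise InputError(f"unknown model {self.model!r}")
        if self.params is None:
            object.__setattr__(self, "params", dict(DEFAULT_ASSAY_PARAMS[self.model]))
        if self.grid is None:
            object.__setattr__(self, "grid", DEFAULT_ASSAY_GRIDS[self.model].copy())
        grid = np.asarray(self.grid, dtype=float)
        object.__setattr__(self, "grid", grid)
        if self.sigma < 0:
            raise InputError("sigma must be >= 0")
        if self.noise not in ("proportional", "additive"):
            raise InputError(f"unknown noise model {self.noise!r}")
        if self.replicates < 1:
            raise InputError("need at least one replicate")
        if self.model in ("michaelis_menten", "hill_binding") and np.any(grid < 0):
            raise InputError("concentrations must be non-negative")
        if self.model == "melt" and np.any(np.diff(grid) <= 0):
            raise InputError("melt temperatures must be strictly increasing")


def _evaluate(model: str, grid: np.ndarray, p: dict) -> np.ndarray:
    if model == "michaelis_menten":
        return michaelis_menten(grid, p["Km"], p["Vmax"])
    if model == "hill_binding":
        return hill_binding(grid, p["Kd"], p["hill"], p["Bmax"])
    return plateau_decay(grid, p["Y0"], p["P"], p["X0"], p["K"])


def simulate_assay(spec: AssaySimSpec) -> list[pd.DataFrame]:
    """One DataFrame per replicate, columns per the target module's input
    contract; replicate r (1-based) is perturbed with an RNG seeded
    ``spec.seed + r``, and sigma = 0 reproduces the model exactly."""
    y_true = _evaluate(spec.model, spec.grid, spec.params)
    xcol, ycol = ASSAY_COLUMNS[spec.model]
    out = []
    for r in range(1, spec.replicates + 1):
        rng = np.random.default_rng(spec.seed + r)
        if spec.sigma == 0:
            y = y_true.copy()
        elif spec.noise == "proportional":
            y = y_true * (1.0 + spec.sigma * rng.standard_normal(y_true.size))
        else:
            y = y_true + spec.sigma * rng.standard_normal(y_true.size)
        out.append(pd.DataFrame({xcol: spec.grid, ycol: y}))
    return out


def melt_params_for_tm(tm: float, x0: float = 50.0, y0: float = -10.0,
                       plateau: float = -1.0) -> dict:
    """Plateau-decay parameters whose midpoint crossing is ``tm``."""
    if tm <= x0:
        raise InputError("Tm must lie past the decay onset X0")
    return {"Y0": y0, "P": plateau, "X0": x0, "K": math.log(2.0) / (tm - x0)}
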