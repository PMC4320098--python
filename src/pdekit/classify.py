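"""Subclass assignment for class III phosphodiesterases.

Three subclasses are distinguished by (i) the motif-IV variant — GNCD marks
subclass IIIC, GNHD/GNHE are shared by IIIA and IIIB — (ii) the lengths of
the four variable inter-motif spacers, and (iii) overall protein size
(averages roughly 285, 243 and 183 aa for IIIA, IIIB and IIIC).

Only the IIIA spacer intervals (37-38, 28-32, 68-70, 35-37) are established
reference values; the shipped IIIB/IIIC intervals are calibration defaults
chosen to be mutually separable and consistent with the subclass size
averages, and can be re-derived from labelled data with
:func:`calibrate_rules` or overridden via a plain-text rule file.
"""

from __future__ import annotations

import configparser
import io
from dataclasses import dataclass

from .errors import CalibrationError, ConfigurationError
from .motifs import SpacerProfile, interval_distance

SUBCLASS_LABELS = ("IIIA", "IIIB", "IIIC")
UNCLASSIFIED = "unclassified"

#: spacer indices that vary between subclasses (0-based; 0 and 5 are fixed at 1)
VARIABLE_SPACERS = (1, 2, 3, 4)


@dataclass(frozen=True)
class SubclassRule:
    """Admissible motif-IV variants, spacer intervals and length interval
    for one subclass."""

    label: str
    motif4_allowed: tuple[str, ...]
    spacer_intervals: tuple[tuple[float, float], ...]  # 6 intervals
    length_interval: tuple[float, float]

    def __post_init__(self) -> None:
        if len(self.spacer_intervals) != 6:
            raise ConfigurationError(f"{self.label}: need 6 spacer intervals")
        for lo, hi in list(self.spacer_intervals) + [self.length_interval]:
            if lo > hi:
                raise ConfigurationError(f"{self.label}: degenerate interval ordering")
        if self.label == "IIIC" and tuple(self.motif4_allowed) != ("GNCD",):
            raise ConfigurationError("IIIC admits only the GNCD motif-IV variant")
        if self.label in ("IIIA", "IIIB") and "GNCD" in self.motif4_allowed:
            raise ConfigurationError(f"{self.label} must not admit GNCD")


@dataclass(frozen=True)
class SubclassRuleTable:
    """Complete rule set: one :class:`SubclassRule` per subclass, the length
    penalty weight (per residue outside the length interval) and the penalty
    threshold above which a sequence is left unclassified."""

    rules: dict[str, SubclassRule]
    length_weight: float = 0.1
    threshold: float = 10.0

    def __post_init__(self) -> None:
        missing = [l for l in SUBCLASS_LABELS if l not in self.rules]
        if missing:
            raise ConfigurationError(f"missing rule entries: {missing}")

    def rule(self, label: str) -> SubclassRule:
        try:
            return self.rules[label]
        except KeyError:
            raise ConfigurationError(f"no rule entry for label {label!r}") from None


@dataclass(frozen=True)
class SubclassCall:
    """Result of classification: a label (or 'unclassified'), the winning
    rule-deviation score, and the evidence it was computed from."""

    label: str
    score: float
    profile: SpacerProfile
    motif4_variant: str


def default_rule_table() -> SubclassRuleTable:
    """Shipped defaults.

    IIIA spacer intervals are the published subclass-A signature; IIIB/IIIC
    intervals are non-authoritative calibration values.  Length intervals are
    +/-15% around the 285/243/183 aa subclass averages.
    """

    def length_band(avg: float) -> tuple[float, float]:
        return (avg * 0.85, avg * 1.15)

    fixed = (1.0, 1.0)
    rules = {
        "IIIA": SubclassRule(
            "IIIA",
            ("GNHD", "GNHE"),
            (fixed, (37, 38), (28, 32), (68, 70), (35, 37), fixed),
            length_band(285),
        ),
        "IIIB": SubclassRule(
            "IIIB",
            ("GNHD", "GNHE"),
            (fixed, (16, 18), (29, 31), (61, 63), (20, 22), fixed),
            length_band(243),
        ),
        "IIIC": SubclassRule(
            "IIIC",
            ("GNCD",),
            (fixed, (13, 15), (29, 31), (27, 29), (11, 13), fixed),
            length_band(183),
        ),
    }
    return SubclassRuleTable(rules)


def rule_score(
    profile: SpacerProfile, rule: SubclassRule, length_weight: float
) -> float:
    """Deviation of a profile from one subclass rule: summed
    distance-to-interval over the four variable spacers plus a weighted
    distance of the sequence length to the length interval."""
    s = sum(
        interval_distance(profile.spacers[i], rule.spacer_intervals[i])
        for i in VARIABLE_SPACERS
    )
    s += length_weight * interval_distance(
        profile.sequence_length, rule.length_interval
    )
    return s


def classify_subclass(
    profile: SpacerProfile,
    motif4_variant: str,
    rules: SubclassRuleTable | None = None,
) -> SubclassCall:
    """Assign a subclass to a spacer profile.

    GNCD forces the IIIC candidate; GNHD/GNHE are scored against IIIA and
    IIIB.  The lowest-scoring admissible label wins (ties broken in the fixed
    order IIIA < IIIB < IIIC); 'unclassified' if the minimum exceeds the
    table's threshold.
    """
    if rules is None:
        rules = default_rule_table()
    if motif4_variant == "GNCD":
        candidates = ["IIIC"]
    else:
        candidates = ["IIIA", "IIIB"]
    scored = [
        (rule_score(profile, rules.rule(label), rules.length_weight), label)
        for label in candidates
    ]
    best_score, best_label = min(scored, key=lambda t: (t[0], t[1]))
    if best_score > rules.threshold:
        return SubclassCall(UNCLASSIFIED, best_score, profile, motif4_variant)
    return SubclassCall(best_label, best_score, profile, motif4_variant)


def calibrate_rules(
    labeled_profiles: list[tuple[SpacerProfile, str, str]],
    margin: int = 0,
    length_weight: float = 0.1,
    threshold: float = 10.0,
) -> SubclassRuleTable:
    """Derive a rule table from labelled (profile, motif4_variant, label)
    triples: per label, each spacer interval and the length interval are the
    min/max over that label's profiles, optionally widened by ``margin``.

    Raises :class:`CalibrationError` for labels with fewer than two profiles,
    missing labels, or contradictory motif-IV evidence (GNCD outside IIIC or
    a non-GNCD variant inside IIIC).
    """
    by_label: dict[str, list[tuple[SpacerProfile, str]]] = {
        l: [] for l in SUBCLASS_LABELS
    }
    for profile, variant, label in labeled_profiles:
        if label not in by_label:
            raise CalibrationError(f"unknown label {label!r}")
        by_label[label].append((profile, variant))

    rules: dict[str, SubclassRule] = {}
    for label, entries in by_label.items():
        if len(entries) < 2:
            raise CalibrationError(
                f"label {label} has {len(entries)} profiles; need at least 2"
            )
        variants = sorted({v for _, v in entries})
        if label == "IIIC":
            if variants != ["GNCD"]:
                raise CalibrationError(
                    f"IIIC profiles carry non-GNCD variants: {variants}"
                )
        elif "GNCD" in variants:
            raise CalibrationError(f"GNCD variant observed under label {label}")
        spacer_cols = list(zip(*(p.spacers for p, _ in entries)))
        intervals = tuple(
            (float(min(col) - margin), float(max(col) + margin))
            for col in spacer_cols
        )
        lengths = [p.sequence_length for p, _ in entries]
        rules[label] = SubclassRule(
            label,
            tuple(variants),
            intervals,
            (float(min(lengths) - margin), float(max(lengths) + margin)),
        )
    return SubclassRuleTable(rules, length_weight=length_weight, threshold=threshold)


# ---------------------------------------------------------------------------
# plain-text rule-table round trip (INI-style)

def rule_table_to_text(table: SubclassRuleTable) -> str:
    cp = configparser.ConfigParser()
    cp["global"] = {
        "length_weight": repr(table.length_weight),
        "threshold": repr(table.threshold),
    }
    for label in SUBCLASS_LABELS:
        r = table.rule(label)
        cp[label] = {
            "variants": ",".join(r.motif4_allowed),
            "spacers": "; ".join(
                f"{float(lo)!r}-{float(hi)!r}" for lo, hi in r.spacer_intervals
            ),
            "length": f"{float(r.length_interval[0])!r}-"
                      f"{float(r.length_interval[1])!r}",
        }
    buf = io.StringIO()
    cp.write(buf)
    return buf.getvalue()


def _parse_interval(text: str) -> tuple[float, float]:
    lo, _, hi = text.strip().partition("-")
    try:
        return (float(lo), float(hi))
    except ValueError:
        raise ConfigurationError(f"bad interval {text!r}") from None


def rule_table_from_text(text: str) -> SubclassRuleTable:
    cp = configparser.ConfigParser()
    try:
        cp.read_string(text)
    except configparser.Error as exc:
        raise ConfigurationError(f"unparseable rule table: {exc}") from exc
    rules = {}
    for label in SUBCLASS_LABELS:
        if label not in cp:
            raise ConfigurationError(f"rule file lacks section [{label}]")
        sec = cp[label]
        rules[label] = SubclassRule(
            label,
            tuple(v.strip() for v in sec["variants"].split(",")),
            tuple(_parse_interval(t) for t in sec["spacers"].split(";")),
            _parse_interval(sec["length"]),
        )
    g = cp["global"] if "global" in cp else {}
    return SubclassRuleTable(
        rules,
        length_weight=float(g.get("length_weight", 0.1)),
        threshold=float(g.get("threshold", 10.0)),
    )
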