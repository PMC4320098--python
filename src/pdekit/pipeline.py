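"""High-level orchestration shared by the CLI and library users."""

from __future__ import annotations

import pandas as pd
from Bio.SeqRecord import SeqRecord

from . import io as pio
from .binding import fit_binding, quench_transform
from .classify import (
    SubclassRuleTable,
    classify_subclass,
    default_rule_table,
)
from .kinetics import derive_constants, fit_mm
from .melting import fit_melt
from .motifs import SignatureDefinition, extract_spacer_profile, scan_architecture
from .phylo import cluster_purity, nj_tree, profile_distance_matrix
from .simulate import permissive_signature


def classify_records(
    records: list[SeqRecord],
    rules: SubclassRuleTable | None = None,
    signature: SignatureDefinition | None = None,
    max_spacer: int = 150,
):
    """Scan and classify every record.

    Returns (report DataFrame, {id: SpacerProfile} for matched records,
    {id: label}).  The scan uses the permissive union signature by default so
    that conformant members of any subclass score penalty 0; the best
    (first-sorted) match per record is classified.
    """
    if rules is None:
        rules = default_rule_table()
    if signature is None:
        signature = permissive_signature(rules)
    rows, profiles, labels = [], {}, {}
    for rec in records:
        matches = scan_architecture(str(rec.seq), signature, max_spacer)
        if not matches:
            rows.append(
                {"id": rec.id, "matched": 0, "positions": "", "spacers": "",
                 "motif4_variant": "", "label": "unclassified", "score": ""}
            )
            continue
        best = matches[0]
        profile = extract_spacer_profile(best, len(rec.seq))
        call = classify_subclass(profile, best.motif4_variant, rules)
        profiles[rec.id] = profile
        labels[rec.id] = call.label
        rows.append(
            {
                "id": rec.id,
                "matched": 1,
                "positions": ",".join(map(str, best.positions)),
                "spacers": ",".join(map(str, best.spacers)),
                "motif4_variant": best.motif4_variant,
                "label": call.label,
                "score": f"{call.score:g}",
            }
        )
    return pio.classification_report(rows), profiles, labels


def classification_tree(profiles, labels, length_weight: float = 0.1):
    """NJ tree over spacer-feature distances plus subclass purity.

    Returns (tree, purity); purity is only meaningful when every subclass has
    several members.
    """
    matrix = profile_distance_matrix(profiles, length_weight)
    tree = nj_tree(matrix)
    purity = cluster_purity(tree, labels)
    return tree, purity


def mm_fit_report(dataset, molar_mass: float) -> dict:
    """Fit Michaelis-Menten data and assemble the JSON fit report."""
    fit = fit_mm(dataset)
    report = {
        "Km": fit.Km, "Km_se": fit.Km_se,
        "Vmax": fit.Vmax, "Vmax_se": fit.Vmax_se,
        "rss": fit.rss, "converged": fit.converged,
    }
    if fit.converged:
        consts = derive_constants(fit, molar_mass)
        report["kcat"] = consts.kcat
        report["efficiency"] = consts.efficiency
        report["molar_mass_kDa"] = molar_mass
    return report


def binding_fit_report(dataset, fix_bmax: float | None = None) -> dict:
    quench = quench_transform(dataset)
    fit = fit_binding(dataset.ligand_conc, quench, fix_bmax=fix_bmax)
    return {
        "Kd": fit.Kd, "hill": fit.hill, "Bmax": fit.Bmax,
        "rss": fit.rss, "converged": fit.converged,
        "cooperativity": fit.cooperativity,
    }


def melt_fit_report(dataset, model: str = "plateau_decay") -> dict:
    fit = fit_melt(dataset, model=model)
    return {
        "Tm": fit.Tm, "X0": fit.X0, "K": fit.K,
        "Y0": fit.native_baseline, "plateau": fit.denatured_plateau,
        "converged": fit.converged,
    }
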