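"""File-format plumbing: FASTA, assay CSVs, rule tables, reports.

All delimited inputs are plain text with mandatory headers:
``substrate_mM,rate_umol_min_mg`` (kinetics), ``conc_mM,F`` (binding; the
first row must be the zero-ligand point) and ``temp_C,theta222`` (melting).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

from .binding import QuenchDataset
from .errors import InputError
from .kinetics import KineticDataset
from .melting import MeltDataset


def read_fasta(path) -> list[SeqRecord]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"no FASTA records in {path}")
    for rec in records:
        if len(rec.seq) == 0:
            raise InputError(f"empty sequence for record {rec.id!r}")
    return records


def write_fasta(records: list[SeqRecord], path) -> None:
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def _read_table(path, required: tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:
        raise InputError(f"unreadable table {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


def read_kinetic_csv(path, substrate_name: str = "") -> KineticDataset:
    df = _read_table(path, ("substrate_mM", "rate_umol_min_mg"))
    return KineticDataset(
        df["substrate_mM"].to_numpy(float),
        df["rate_umol_min_mg"].to_numpy(float),
        substrate_name,
    )


def read_quench_csv(path) -> QuenchDataset:
    """Binding titration CSV ``conc_mM,F``; the first row is the zero-ligand
    point and defines F0."""
    df = _read_table(path, ("conc_mM", "F"))
    conc = df["conc_mM"].to_numpy(float)
    f = df["F"].to_numpy(float)
    if conc.size == 0 or conc[0] != 0:
        raise InputError("first row must be the zero-ligand (conc_mM = 0) point")
    return QuenchDataset(conc, f, float(f[0]))


def read_melt_csv(path) -> MeltDataset:
    df = _read_table(path, ("temp_C", "theta222"))
    return MeltDataset(df["temp_C"].to_numpy(float), df["theta222"].to_numpy(float))


def quench_to_fluorescence(df: pd.DataFrame, F0: float = 100.0) -> pd.DataFrame:
    """Convert a simulated (conc_mM, quench) table to the (conc_mM, F) input
    contract with basal fluorescence ``F0``."""
    if "quench" not in df.columns:
        raise InputError("expected a 'quench' column")
    out = pd.DataFrame({"conc_mM": df["conc_mM"], "F": F0 * (1.0 - df["quench"])})
    return out


def classification_report(rows: list[dict]) -> pd.DataFrame:
    """One row per record: id, matched, positions, spacers, motif4_variant,
    label, score."""
    cols = ["id", "matched", "positions", "spacers", "motif4_variant", "label", "score"]
    return pd.DataFrame(rows, columns=cols)


def write_report_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_json(obj: dict, path) -> None:
    def _default(x):
        if isinstance(x, (np.floating, np.integer)):
            return x.item()
        raise TypeError(f"not JSON-serializable: {type(x)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")
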