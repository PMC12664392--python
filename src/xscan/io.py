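"""Delimited-text and JSON I/O for pipeline inputs and outputs.

Activation matrices travel as long-format TSV with a ``#wt=`` header line::

    #wt=SLLMWITQV
    replicate	position	residue	value
    rep1	1	A	72.3
    ...

Positions are 1-based; residues are one-letter codes; values are percent
activation.  Tolerance profiles and motifs are stored as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .activation import ActivationMatrix, ToleranceProfile
from .motif import PeptideMotif, emit_motif, parse_motif


def read_activation_tsv(path) -> list[ActivationMatrix]:
    """Read replicate activation matrices from long-format TSV."""
    path = Path(path)
    lines = path.read_text().splitlines()
    wt = None
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#wt="):
            wt = line[len("#wt="):].strip()
        elif line.startswith("#"):
            continue
        else:
            body_start = i
            break
    if wt is None:
        raise ValueError(f"{path}: missing '#wt=' header line")
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"replicate", "position", "residue", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    matrices = []
    for rep, grp in df.groupby("replicate", sort=True):
        wide = grp.pivot_table(
            index="position", columns="residue", values="value", aggfunc="mean"
        )
        wide = wide.reindex(range(1, len(wt) + 1))
        wide.index.name = None
        wide.columns.name = None
        matrices.append(
            ActivationMatrix(wild_type=wt, values=wide, normalized=False, replicate=str(rep))
        )
    return matrices


def write_activation_tsv(path, matrices: list[ActivationMatrix]) -> None:
    """Write replicate matrices as long-format TSV with the ``#wt=`` header."""
    if not matrices:
        raise ValueError("no matrices to write")
    wt = matrices[0].wild_type
    rows = []
    for m in matrices:
        if m.wild_type != wt:
            raise ValueError("matrices disagree on wild type")
        rep = m.replicate or "rep1"
        long = m.values.stack().reset_index()
        long.columns = ["position", "residue", "value"]
        long.insert(0, "replicate", rep)
        rows.append(long)
    out = pd.concat(rows, ignore_index=True)
    with open(path, "w") as fh:
        fh.write(f"#wt={wt}\n")
        out.to_csv(fh, sep="\t", index=False)


def profile_to_json(profile: ToleranceProfile) -> dict:
    return {
        "wild_type": profile.wild_type,
        "threshold": profile.threshold,
        "allowed": ["".join(sorted(s)) for s in profile.allowed],
        "motif": emit_motif(profile.to_motif()),
    }


def profile_from_json(obj: dict) -> ToleranceProfile:
    return ToleranceProfile(
        wild_type=obj["wild_type"],
        allowed=tuple(frozenset(s) for s in obj["allowed"]),
        threshold=float(obj.get("threshold", 30.0)),
    )


def write_profile(path, profile: ToleranceProfile) -> None:
    Path(path).write_text(json.dumps(profile_to_json(profile), indent=2) + "\n")


def read_profile(path) -> ToleranceProfile:
    return profile_from_json(json.loads(Path(path).read_text()))


def read_motifs(path) -> list[PeptideMotif]:
    """Read motifs from JSON: ``{"motifs": [{"id": ..., "pattern": ...}]}``."""
    obj = json.loads(Path(path).read_text())
    entries = obj["motifs"] if isinstance(obj, dict) else obj
    return [parse_motif(e["pattern"], motif_id=e.get("id", "")) for e in entries]


def write_motifs(path, motifs: list[PeptideMotif]) -> None:
    obj = {"motifs": [{"id": m.id, "pattern": emit_motif(m)} for m in motifs]}
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")


def write_fasta(path, records) -> None:
    """Write proteome records as FASTA (60-column wrap)."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id else (
                f"{rec.id} {rec.description}"
            )
            fh.write(f">{header}\n")
            seq = rec.sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_dose_response_tsv(path) -> pd.DataFrame:
    """TSV with columns dose_molar, response[, group]."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"dose_molar", "response"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_lysis_tsv(path) -> pd.DataFrame:
    """TSV with columns well, experimental, spontaneous, maximum."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"experimental", "spontaneous", "maximum"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_htrf_tsv(path) -> pd.DataFrame:
    """TSV with columns clone_id, signal_target, then one column per control."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"clone_id", "signal_target"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df
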