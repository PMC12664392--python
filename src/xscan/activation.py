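"""Positional-scanning (X-scan / alanine-scan) activation matrices.

An X-scan substitutes every position of a reference 9-mer epitope with each
of the 19 alternative residues and measures the functional readout
(% IFNγ-positive CD8+ T cells) for every variant.  This module turns raw
replicate matrices into a wild-type-normalized matrix, a per-position
tolerance profile, and alanine-scan sensitivity calls.

Pipeline order is fixed: replicates are averaged first, then the averaged
matrix is normalized to 100% at the wild-type residue of each position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
"""The 20 canonical residues, alphabetical one-letter codes."""

#: Default tolerance threshold in % of wild-type activation.  A substitution
#: is called tolerated when its normalized activation strictly exceeds this.
DEFAULT_THRESHOLD: float = 30.0


def _check_sequence(seq: str) -> str:
    if not seq:
        raise ValueError("wild-type sequence must be non-empty")
    seq = seq.upper()
    bad = sorted(set(seq) - set(AMINO_ACIDS))
    if bad:
        raise ValueError(f"non-canonical residues in wild-type sequence: {bad}")
    return seq


@dataclass
class ActivationMatrix:
    """Position x residue activation matrix for one replicate (or an average).

    Parameters
    ----------
    wild_type
        Reference peptide sequence (uppercase, canonical alphabet).
    values
        DataFrame indexed by 1-based position, columns are one-letter
        residues, cells are percent activation (>= 0; values above 100 are
        legal — a variant may outperform the wild type).
    normalized
        True once the matrix has been scaled so the wild-type cell of every
        position is exactly 100.
    replicate
        Optional replicate label, carried through I/O.
    """

    wild_type: str
    values: pd.DataFrame
    normalized: bool = False
    replicate: str | None = None

    def __post_init__(self) -> None:
        self.wild_type = _check_sequence(self.wild_type)
        vals = self.values
        if not isinstance(vals, pd.DataFrame):
            raise TypeError("values must be a pandas DataFrame")
        vals = vals.astype(float)
        vals.index = vals.index.astype(int)
        expected = pd.RangeIndex(1, len(self.wild_type) + 1)
        if not vals.index.equals(pd.Index(expected)):
            raise ValueError(
                f"positions must be 1..{len(self.wild_type)}, got {list(vals.index)}"
            )
        bad_cols = sorted(set(vals.columns) - set(AMINO_ACIDS))
        if bad_cols:
            raise ValueError(f"non-canonical residue columns: {bad_cols}")
        present = vals.to_numpy()
        if not np.all(np.isfinite(present) | np.isnan(present)):
            raise ValueError("activation values must be finite")
        if np.nanmin(present) < 0:
            raise ValueError("activation values must be >= 0")
        for pos, wt_res in self.positions_wt():
            if wt_res not in vals.columns or math.isnan(vals.at[pos, wt_res]):
                raise ValueError(
                    f"wild-type cell missing at position {pos} ({wt_res})"
                )
            if self.normalized and vals.at[pos, wt_res] != 100.0:
                raise ValueError(
                    f"normalized matrix must have wild-type cell == 100 at "
                    f"position {pos}, got {vals.at[pos, wt_res]}"
                )
        self.values = vals

    def __len__(self) -> int:
        return len(self.wild_type)

    def positions_wt(self) -> Iterable[tuple[int, str]]:
        """Yield (1-based position, wild-type residue) pairs."""
        return enumerate(self.wild_type, start=1)

    def cell(self, position: int, residue: str) -> float:
        """Activation value for one variant; NaN when not measured."""
        if residue not in self.values.columns:
            return float("nan")
        return float(self.values.at[position, residue])


@dataclass(frozen=True)
class ToleranceProfile:
    """Per-position sets of residues tolerated by the binder.

    A residue is tolerated at a position when its wild-type-normalized
    activation strictly exceeds ``threshold``.  The wild-type residue is a
    member of every set by construction (its normalized value is 100).
    """

    wild_type: str
    allowed: tuple[frozenset[str], ...]
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        object.__setattr__(self, "wild_type", _check_sequence(self.wild_type))
        if len(self.allowed) != len(self.wild_type):
            raise ValueError("one allowed set per position is required")
        allowed = tuple(frozenset(s) for s in self.allowed)
        for i, (s, wt_res) in enumerate(zip(allowed, self.wild_type), start=1):
            if not s:
                raise ValueError(f"empty allowed set at position {i}")
            bad = sorted(s - set(AMINO_ACIDS))
            if bad:
                raise ValueError(f"non-canonical residues at position {i}: {bad}")
            if wt_res not in s:
                raise ValueError(
                    f"wild-type residue {wt_res} missing from allowed set at "
                    f"position {i}"
                )
        object.__setattr__(self, "allowed", allowed)

    def to_motif(self, motif_id: str = ""):
        """Serialize to a :class:`~xscan.motif.PeptideMotif`."""
        from .motif import PeptideMotif

        return PeptideMotif(classes=self.allowed, id=motif_id)


@dataclass(frozen=True)
class AlanineScanResult:
    """Alanine-scan sensitivity calls.

    ``values`` maps a position label to the normalized activation of the
    corresponding alanine variant.  The two MHC anchor positions (p2/p9 for
    HLA-A*02:01 9-mers) are mutated jointly in the assay and appear as a
    single pseudo-position labelled e.g. ``"2+9"``.  A position is flagged
    sensitive when its alanine-variant activation is at or below the
    threshold — i.e. alanine substitution abolishes recognition.
    """

    values: Mapping[str, float]
    threshold: float
    sensitive: Mapping[str, bool]
    note: str = ""

    def __post_init__(self) -> None:
        for label, flag in self.sensitive.items():
            expected = self.values[label] <= self.threshold
            if flag != expected:
                raise ValueError(f"inconsistent sensitivity flag at {label}")


def average_replicates(matrices: Sequence[ActivationMatrix]) -> ActivationMatrix:
    """Cell-wise arithmetic mean of replicate activation matrices.

    All replicates must share the wild-type sequence and cover the same
    (position, residue) cells; a cell missing in any replicate is an error
    (silent imputation would bias the downstream tolerance sets).
    A single replicate is returned as an (un-normalized) copy.
    """
    if not matrices:
        raise ValueError("at least one replicate is required")
    ref = matrices[0]
    for m in matrices[1:]:
        if m.wild_type != ref.wild_type:
            raise ValueError(
                f"replicates disagree on wild type: {m.wild_type!r} != "
                f"{ref.wild_type!r}"
            )
        if list(m.values.columns) != list(ref.values.columns) or not m.values.index.equals(
            ref.values.index
        ):
            raise ValueError("replicates must cover identical positions and residues")
    stack = [m.values for m in matrices]
    for m in matrices:
        if m.values.isna().any().any():
            pos = m.values.isna().stack()
            where = pos[pos].index[0]
            raise ValueError(
                f"missing cell at position {where[0]}, residue {where[1]} "
                f"in replicate {m.replicate!r}"
            )
    mean = sum(stack) / len(stack)
    return ActivationMatrix(
        wild_type=ref.wild_type, values=mean, normalized=False, replicate=None
    )


def normalize_to_wildtype(matrix: ActivationMatrix) -> ActivationMatrix:
    """Scale each position so the wild-type cell reads exactly 100%.

    Every value at position *i* is multiplied by ``100 / value(i, wt_i)``.
    Applying the operation twice is rejected — renormalizing an already
    normalized matrix is a pipeline error, not a no-op.
    """
    if matrix.normalized:
        raise ValueError("matrix is already normalized")
    vals = matrix.values.copy()
    for pos, wt_res in matrix.positions_wt():
        wt_val = vals.at[pos, wt_res]
        if math.isnan(wt_val) or wt_val <= 0:
            raise ValueError(
                f"wild-type activation at position {pos} ({wt_res}) is "
                f"{wt_val}; normalization undefined"
            )
        # v/wt == 1.0 exactly for the WT cell, so WT cells become exactly 100
        vals.loc[pos] = (vals.loc[pos] / wt_val) * 100.0
    return ActivationMatrix(
        wild_type=matrix.wild_type,
        values=vals,
        normalized=True,
        replicate=matrix.replicate,
    )


def tolerated_sets(
    matrix: ActivationMatrix, threshold: float = DEFAULT_THRESHOLD
) -> ToleranceProfile:
    """Call tolerated substitutions from a normalized matrix.

    Residue ``r`` is tolerated at position ``i`` iff its normalized
    activation strictly exceeds ``threshold`` (in %).  The wild type is
    included by construction: its normalized value is exactly 100.
    """
    if not matrix.normalized:
        raise ValueError("tolerated_sets requires a normalized matrix")
    if not 0 <= threshold < 100:
        raise ValueError("threshold must lie in [0, 100)")
    allowed = []
    for pos, _ in matrix.positions_wt():
        row = matrix.values.loc[pos]
        members = frozenset(res for res, v in row.items() if v > threshold)
        allowed.append(members)
    return ToleranceProfile(
        wild_type=matrix.wild_type, allowed=tuple(allowed), threshold=threshold
    )


def alanine_sensitivity(
    matrix: ActivationMatrix,
    threshold: float = DEFAULT_THRESHOLD,
    anchor_positions: tuple[int, int] | None = (2, 9),
    joint_anchor_value: float | None = None,
) -> AlanineScanResult:
    """Flag positions where alanine substitution abolishes T-cell activation.

    Non-anchor positions are read from the matrix's alanine column.  The two
    MHC anchor positions are mutated simultaneously in the assay (a single
    double-substituted peptide), supplied as ``joint_anchor_value`` and
    reported under one pseudo-position label such as ``"2+9"``.

    A position whose wild-type residue already is alanine reads 100
    (the wild-type cell) and is never flagged sensitive.
    """
    if not matrix.normalized:
        raise ValueError("alanine_sensitivity requires a normalized matrix")
    values: dict[str, float] = {}
    anchors = set(anchor_positions or ())
    for pos, _ in matrix.positions_wt():
        if pos in anchors:
            continue
        v = matrix.cell(pos, "A")
        if math.isnan(v):
            raise ValueError(f"alanine cell missing at position {pos}")
        values[str(pos)] = v
    note = ""
    if anchors:
        if joint_anchor_value is None:
            raise ValueError(
                "joint_anchor_value is required when anchor positions are set "
                "(anchors are mutated simultaneously)"
            )
        label = "+".join(str(p) for p in sorted(anchors))
        values[label] = float(joint_anchor_value)
        note = f"positions {label} mutated simultaneously (MHC anchors)"
    sensitive = {label: v <= threshold for label, v in values.items()}
    return AlanineScanResult(
        values=values, threshold=threshold, sensitive=sensitive, note=note
    )
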