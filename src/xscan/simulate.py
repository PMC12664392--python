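"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the study's data-generating conditions so each stage
can be tested end-to-end without any downloads: replicate X-scan activation
matrices drawn around a designed tolerance structure, proteomes with
planted motif matches, noisy three-parameter dose-response curves, and toy
coordinate sets with analytically known surface areas.

All randomness flows through ``numpy.random.default_rng`` (PCG64), so every
generator is fully deterministic per seed across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .activation import AMINO_ACIDS, ActivationMatrix, ToleranceProfile
from .motif import ProteomeRecord
from .structure import Atom, Chain, Residue, Structure


@dataclass(frozen=True)
class XscanSimSpec:
    """Conditions for simulating replicate X-scan activation matrices.

    Tolerated (active) cells are drawn from Normal(active_mean, noise_sd),
    non-tolerated cells from Normal(inactive_mean, noise_sd), both truncated
    at 0 (the %-activation scale has no negative values).  The separation
    ``active_mean − inactive_mean > 4·noise_sd`` is enforced so that the
    30% threshold sits many standard deviations from both levels and
    profile recovery is near-certain by construction.
    """

    profile: ToleranceProfile
    active_mean: float = 80.0
    inactive_mean: float = 5.0
    noise_sd: float = 5.0
    replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("at least one replicate is required")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.active_mean - self.inactive_mean <= 4 * self.noise_sd:
            raise ValueError(
                "separability violated: active_mean - inactive_mean must "
                "exceed 4 * noise_sd"
            )


def gen_xscan(spec: XscanSimSpec) -> tuple[list[ActivationMatrix], ToleranceProfile]:
    """Simulate replicate activation matrices around a target profile.

    Every cell (position x 20 residues) is populated; wild-type cells are
    drawn from the active distribution (they are tolerated by definition).
    Returns the replicates (un-normalized) and the ground-truth profile.
    """
    rng = np.random.default_rng(spec.seed)
    profile = spec.profile
    L = len(profile.wild_type)
    residues = list(AMINO_ACIDS)
    matrices = []
    for rep in range(spec.replicates):
        data = np.empty((L, 20))
        for i, allowed in enumerate(profile.allowed):
            means = np.array(
                [spec.active_mean if r in allowed else spec.inactive_mean for r in residues]
            )
            data[i] = means + rng.normal(0.0, spec.noise_sd, size=20)
        data = np.clip(data, 0.0, None)
        values = pd.DataFrame(data, index=range(1, L + 1), columns=residues)
        matrices.append(
            ActivationMatrix(
                wild_type=profile.wild_type,
                values=values,
                normalized=False,
                replicate=f"rep{rep + 1}",
            )
        )
    return matrices, profile


@dataclass(frozen=True)
class ProteomeSimSpec:
    """Conditions for simulating a proteome with planted motif matches.

    ``planted`` lists (protein_index, offset, peptide) triples; offsets are
    1-based.  Background residues are drawn from ``residue_freqs`` (uniform
    over the 20 canonical residues by default).
    """

    n_proteins: int = 50
    mean_length: int = 300
    min_length: int = 50
    planted: tuple[tuple[int, int, str], ...] = ()
    residue_freqs: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.min_length < 1:
            raise ValueError("n_proteins and min_length must be >= 1")
        if self.residue_freqs is not None:
            freqs = np.asarray(self.residue_freqs, dtype=float)
            if freqs.shape != (20,) or np.any(freqs < 0) or freqs.sum() <= 0:
                raise ValueError("residue_freqs must be 20 non-negative weights")


#: Approximate UniProt/SwissProt background residue frequencies,
#: ordered as AMINO_ACIDS (A..Y alphabetical one-letter order).
UNIPROT_FREQS: tuple[float, ...] = (
    0.0826, 0.0137, 0.0546, 0.0672, 0.0386, 0.0708, 0.0227, 0.0591, 0.0580,
    0.0965, 0.0241, 0.0406, 0.0474, 0.0393, 0.0553, 0.0665, 0.0535, 0.0686,
    0.0110, 0.0292,
)


def gen_proteome(
    spec: ProteomeSimSpec,
) -> tuple[list[ProteomeRecord], pd.DataFrame]:
    """Random protein sequences with planted peptides at recorded offsets.

    Returns FASTA-ready records and a manifest of every guaranteed hit
    (protein_id, offset, peptide).  Overlapping planted sites are rejected —
    splicing one planted peptide into another would corrupt both.
    """
    rng = np.random.default_rng(spec.seed)
    freqs = (
        np.asarray(spec.residue_freqs, dtype=float)
        if spec.residue_freqs is not None
        else np.full(20, 1.0 / 20.0)
    )
    freqs = freqs / freqs.sum()
    residues = np.array(list(AMINO_ACIDS))

    lengths = np.maximum(
        rng.poisson(spec.mean_length, size=spec.n_proteins), spec.min_length
    )
    seqs = [
        list(rng.choice(residues, size=n, p=freqs)) for n in lengths
    ]

    occupied: dict[int, set[int]] = {}
    manifest_rows = []
    for prot_idx, offset, peptide in spec.planted:
        if not 0 <= prot_idx < spec.n_proteins:
            raise ValueError(f"planted protein index {prot_idx} out of range")
        start = offset - 1
        end = start + len(peptide)
        if start < 0 or end > len(seqs[prot_idx]):
            raise ValueError(
                f"planted peptide {peptide!r} does not fit in protein "
                f"{prot_idx} at offset {offset}"
            )
        span = set(range(start, end))
        if occupied.setdefault(prot_idx, set()) & span:
            raise ValueError(
                f"planted sites collide in protein {prot_idx}; choose "
                f"different offsets or a different seed"
            )
        occupied[prot_idx] |= span
        seqs[prot_idx][start:end] = list(peptide.upper())
        manifest_rows.append(
            {"protein_id": f"SYN{prot_idx:04d}", "offset": offset, "peptide": peptide.upper()}
        )

    records = [
        ProteomeRecord(
            id=f"SYN{i:04d}",
            sequence="".join(seq),
            description=f"synthetic protein {i}",
        )
        for i, seq in enumerate(seqs)
    ]
    manifest = pd.DataFrame(manifest_rows, columns=["protein_id", "offset", "peptide"])
    return records, manifest


def gen_dose_response(
    bottom: float,
    top: float,
    ec50: float,
    doses: Sequence[float],
    sigma: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Exact three-parameter logistic responses plus Gaussian noise."""
    from .assays import three_parameter_logistic

    doses = np.asarray(doses, dtype=float)
    if doses.size == 0:
        raise ValueError("dose list must be non-empty")
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    rng = np.random.default_rng(seed)
    resp = three_parameter_logistic(doses, bottom, top, ec50)
    if sigma > 0:
        resp = resp + rng.normal(0.0, sigma, size=doses.shape)
    return pd.DataFrame({"dose_molar": doses, "response": resp})


def gen_toy_structure(kind: str, distance: float = 6.0) -> Structure:
    """Handcrafted coordinate sets with analytically known properties.

    ``single_atom``
        One carbon atom: SASA is the full inflated sphere, 4π(1.70+probe)².
    ``two_spheres``
        Two carbon atoms ``distance`` Å apart: SASA follows the
        spherical-cap formula when the inflated spheres overlap.
    ``mini_interface``
        Two three-residue polyalanine strands on separate chains ~4.5 Å
        apart: CB–CB pairs give hydrophobic contacts and no hydrogen bonds
        form between the strands at that spacing.
    """
    if kind == "single_atom":
        return Structure(
            id="single_atom",
            chains=[
                Chain(
                    id="A",
                    residues=[
                        Residue(name="ALA", seq_id=1, atoms=[Atom("CB", "C", (0.0, 0.0, 0.0))])
                    ],
                )
            ],
        )
    if kind == "two_spheres":
        return Structure(
            id="two_spheres",
            chains=[
                Chain(
                    id="A",
                    residues=[
                        Residue(name="ALA", seq_id=1, atoms=[Atom("CB", "C", (0.0, 0.0, 0.0))]),
                        Residue(
                            name="ALA", seq_id=2, atoms=[Atom("CB", "C", (distance, 0.0, 0.0))]
                        ),
                    ],
                )
            ],
        )
    if kind == "mini_interface":
        # Idealized extended strands: backbone N, CA, C, O + CB per residue,
        # CA spacing 3.8 Å along x; strand B offset 4.5 Å in z so the CB
        # atoms (pointing toward each other) sit ~4 Å apart.
        def strand(chain_id: str, z: float, cb_dz: float, start_id: int) -> Chain:
            residues = []
            for i in range(3):
                x = i * 3.8
                atoms = [
                    Atom("N", "N", (x - 1.2, 0.5, z)),
                    Atom("CA", "C", (x, 0.0, z)),
                    Atom("C", "C", (x + 1.2, 0.6, z)),
                    Atom("O", "O", (x + 1.3, 1.8, z)),
                    Atom("CB", "C", (x, -0.4, z + cb_dz)),
                ]
                residues.append(Residue(name="ALA", seq_id=start_id + i, atoms=atoms))
            return Chain(id=chain_id, residues=residues)

        return Structure(
            id="mini_interface",
            chains=[strand("A", 0.0, 1.2, 1), strand("B", 6.0, -1.2, 1)],
        )
    raise ValueError(f"unknown toy structure kind {kind!r}")
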