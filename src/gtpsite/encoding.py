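"""Sliding-window feature encoding.

Each residue of a protein becomes one classification instance: a window
of ``w`` consecutive residues centred on it (``w`` odd), encoded as a
fixed-length real vector.  The primary encoding scales the 20 PSSM
log-odds scores of every window position through the logistic function
``F(x) = 1 / (1 + exp(-x))`` so all features live in (0, 1); with the
default window of 19 this yields 19 x 20 = 380 features per residue.
Alternative encodings substitute one-hot (BINARY) or substitution-matrix
(BLOSUM62 / PAM250) rows for the PSSM rows.

Window positions beyond the termini are padded with '-' and contribute
exact-zero feature blocks, which keeps "beyond the terminus" machine-
distinguishable from a zero log-odds score (which maps to 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

import numpy as np
from Bio.Align import substitution_matrices

from .io_formats import (
    PAD,
    PSSM_COLUMNS,
    ParameterError,
    ConsistencyError,
    ProteinRecord,
    PSSMProfile,
)

SUBSTITUTION_NAMES = ("BINARY", "BLOSUM62", "PAM250")


@dataclass
class WindowFragment:
    """A length-``w`` residue window centred on one residue.

    ``center`` is the 0-based index of the central residue in its
    protein; ``residues`` uses '-' for positions beyond the termini;
    ``label`` is 1 for an annotated binding residue.
    """

    protein_id: str
    center: int
    residues: str
    label: int

    @property
    def w(self) -> int:
        return len(self.residues)


def logistic_scale(x):
    """Logistic squashing ``1 / (1 + exp(-x))`` of PSSM log-odds scores."""
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def extract_windows(record: ProteinRecord, w: int) -> List[WindowFragment]:
    """One window per residue of ``record`` (all residues become instances).

    Positions outside the sequence are filled with '-'.  The label is 1
    iff the (1-based) centre position is annotated as binding.
    """
    if w % 2 == 0 or w < 1:
        raise ParameterError(f"window size must be odd and positive, got {w}")
    half = (w - 1) // 2
    seq = record.sequence
    n = len(seq)
    padded = PAD * half + seq + PAD * half
    fragments = []
    for i in range(n):
        fragments.append(
            WindowFragment(
                protein_id=record.id,
                center=i,
                residues=padded[i : i + w],
                label=1 if (i + 1) in record.binding_positions else 0,
            )
        )
    return fragments


def encode_pssm_window(profile: PSSMProfile, fragment: WindowFragment) -> np.ndarray:
    """Encode a window from its PSSM rows, logistic-scaled, length ``20*w``."""
    if profile.protein_id != fragment.protein_id:
        raise ConsistencyError(
            f"profile {profile.protein_id!r} does not match fragment "
            f"{fragment.protein_id!r}"
        )
    n = len(profile)
    if not (0 <= fragment.center < n):
        raise ConsistencyError(
            f"fragment centre {fragment.center} outside profile of length {n}"
        )
    w = fragment.w
    half = (w - 1) // 2
    out = np.zeros((w, 20), dtype=float)
    lo = fragment.center - half
    for k in range(w):
        pos = lo + k
        if 0 <= pos < n:
            out[k] = logistic_scale(profile.scores[pos])
    return out.ravel()


@dataclass
class SubstitutionEncoding:
    """A per-residue 20-vector lookup table (one-hot or substitution matrix)."""

    name: str
    table: Dict[str, np.ndarray]

    def row(self, residue: str) -> np.ndarray:
        """20-vector for ``residue``; zeros for padding and ambiguity codes."""
        return self.table.get(residue, np.zeros(20))


def substitution_encoding(name: str) -> SubstitutionEncoding:
    """Build a named encoding table over :data:`PSSM_COLUMNS` order.

    BINARY rows are one-hot and used raw; BLOSUM62 and PAM250 rows are
    passed through :func:`logistic_scale` so every encoding shares the
    (0, 1) range of the PSSM features (unscaled integer substitution
    scores would dominate Euclidean distances in the RBF kernel).
    """
    name = name.upper()
    if name not in SUBSTITUTION_NAMES:
        raise ParameterError(
            f"unknown encoding {name!r}; expected one of {SUBSTITUTION_NAMES}"
        )
    table: Dict[str, np.ndarray] = {}
    if name == "BINARY":
        for i, aa in enumerate(PSSM_COLUMNS):
            row = np.zeros(20)
            row[i] = 1.0
            table[aa] = row
    else:
        matrix = substitution_matrices.load(name)
        for aa in PSSM_COLUMNS:
            raw = np.array([matrix[aa, bb] for bb in PSSM_COLUMNS], dtype=float)
            table[aa] = logistic_scale(raw)
    return SubstitutionEncoding(name=name, table=table)


def encode_substitution_window(
    record: ProteinRecord, fragment: WindowFragment, encoding: SubstitutionEncoding
) -> np.ndarray:
    """Encode a window by per-position table lookup, length ``20*w``."""
    if encoding.name not in SUBSTITUTION_NAMES:
        raise ParameterError(f"unknown encoding {encoding.name!r}")
    if record.id != fragment.protein_id:
        raise ConsistencyError(
            f"record {record.id!r} does not match fragment "
            f"{fragment.protein_id!r}"
        )
    return np.concatenate([encoding.row(res) for res in fragment.residues])
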