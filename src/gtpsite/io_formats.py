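"""File formats and shared domain types.

This module owns every format the pipeline touches — FASTA sequences,
PSI-BLAST ASCII PSSM profiles, binding-site annotation tables and
prediction tables — together with the domain types the rest of the
package passes around.

Coordinate convention: every external file is 1-based (UniProt style);
everything in memory past this module is 0-based.  This module is the
only place the conversion happens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard amino acids in PSI-BLAST PSSM column order.
PSSM_COLUMNS = "ARNDCQEGHILKMFPSTWYV"

#: Ambiguity / non-standard codes accepted in input sequences.
AMBIGUITY_CODES = "XBZUO"

#: Full accepted sequence alphabet.
SEQUENCE_ALPHABET = set(PSSM_COLUMNS) | set(AMBIGUITY_CODES)

#: Padding symbol used for window positions beyond the termini.
PAD = "-"


class FormatError(ValueError):
    """A file does not conform to its expected format."""


class ConsistencyError(ValueError):
    """Two inputs that must agree (lengths, identifiers) do not."""


class ParameterError(ValueError):
    """A caller-supplied parameter is outside its contract."""


@dataclass
class ProteinRecord:
    """A protein sequence with its annotated binding residues.

    Parameters
    ----------
    id : str
        Accession-like identifier; non-empty, no whitespace.
    sequence : str
        Upper-case amino-acid sequence (standard 20 letters plus the
        ambiguity codes X, B, Z, U, O).
    binding_positions : set of int
        1-based positions of residues annotated as GTP-binding.
    """

    id: str
    sequence: str
    binding_positions: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"invalid protein id {self.id!r}")
        if len(self.sequence) < 1:
            raise FormatError(f"empty sequence for {self.id}")
        bad = set(self.sequence) - SEQUENCE_ALPHABET
        if bad:
            raise FormatError(
                f"sequence of {self.id} contains invalid character(s) "
                f"{sorted(bad)}"
            )
        for p in self.binding_positions:
            if not (1 <= p <= len(self.sequence)):
                raise ConsistencyError(
                    f"binding position {p} outside 1..{len(self.sequence)} "
                    f"for {self.id}"
                )

    @property
    def n_positive(self) -> int:
        return len(self.binding_positions)


@dataclass
class PSSMProfile:
    """Per-residue log-odds profile for one protein.

    ``scores`` has one row per residue and one column per amino acid in
    :data:`PSSM_COLUMNS` order.
    """

    protein_id: str
    scores: np.ndarray
    column_order: str = PSSM_COLUMNS

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ConsistencyError(
                f"PSSM for {self.protein_id} must have 20 columns, got shape "
                f"{self.scores.shape}"
            )

    def __len__(self) -> int:
        return self.scores.shape[0]


@dataclass
class PredictionRecord:
    """One scored residue: positive-node minus negative-node output."""

    protein_id: str
    position: int  # 1-based
    score: float
    label: int


SiteAnnotationTable = Dict[str, List[int]]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> List[ProteinRecord]:
    """Read a multi-record FASTA file.

    The record id is the first whitespace-delimited header token;
    sequences are upper-cased and line wrapping is immaterial.
    ``binding_positions`` is left empty — annotations are attached from a
    separate table.
    """
    path = Path(path)
    records: List[ProteinRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper().replace(" ", "")
        bad = set(seq) - SEQUENCE_ALPHABET
        if bad:
            ch = sorted(bad)[0]
            raise FormatError(
                f"{path}: record {entry.id!r} position "
                f"{seq.index(ch) + 1}: invalid sequence character {ch!r}"
            )
        records.append(ProteinRecord(id=entry.id, sequence=seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM


def _is_pssm_row(tokens: Sequence[str]) -> bool:
    return (
        len(tokens) >= 22
        and tokens[0].isdigit()
        and len(tokens[1]) == 1
        and tokens[1].isalpha()
    )


def read_pssm_ascii(path, expected_length: int, sequence: str | None = None) -> PSSMProfile:
    """Read the 20 log-odds columns of a PSI-BLAST ``-out_ascii_pssm`` file.

    Parameters
    ----------
    path : path-like
        ASCII PSSM file (header lines, one row per residue with residue
        index, residue letter, 20 log-odds integers and further columns
        which are ignored).
    expected_length : int
        Length of the paired sequence; a row-count mismatch raises
        :class:`ConsistencyError`.
    sequence : str, optional
        When given, residue letters in the file are checked against it;
        disagreements are logged as warnings, never fatal (PSI-BLAST
        outputs occasionally normalise ambiguity codes).
    """
    path = Path(path)
    rows: List[List[int]] = []
    letters: List[str] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not _is_pssm_row(tokens):
                continue
            try:
                rows.append([int(t) for t in tokens[2:22]])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: unparseable PSSM row: {line.rstrip()!r}"
                ) from exc
            letters.append(tokens[1].upper())
    if len(rows) != expected_length:
        raise ConsistencyError(
            f"{path}: {len(rows)} PSSM rows but expected {expected_length}"
        )
    if sequence is not None:
        for i, (a, b) in enumerate(zip(letters, sequence.upper())):
            if a != b:
                logger.warning(
                    "%s: residue mismatch at position %d (PSSM %r vs sequence %r)",
                    path, i + 1, a, b,
                )
    profile_id = path.stem
    return PSSMProfile(protein_id=profile_id, scores=np.array(rows, dtype=np.int64))


def write_pssm_ascii(profile: PSSMProfile, sequence: str, path) -> None:
    """Write a profile in the PSI-BLAST ASCII dialect :func:`read_pssm_ascii` consumes.

    Percentage columns and information-content trailers are emitted as
    zeros — they are ignored on read.
    """
    if len(sequence) != len(profile):
        raise ConsistencyError(
            f"sequence length {len(sequence)} != profile rows {len(profile)}"
        )
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed\n")
        header = " ".join(f"{a:>3}" for a in profile.column_order)
        fh.write("          " + header + "  " + header + "\n")
        for i, (res, row) in enumerate(zip(sequence, profile.scores), start=1):
            scores = " ".join(f"{int(v):>3d}" for v in row)
            pct = " ".join(f"{0:>3d}" for _ in row)
            fh.write(f"{i:>5d} {res} {scores}  {pct}  0.00 0.00\n")


# ---------------------------------------------------------------------------
# Annotations


def read_site_annotations(path) -> SiteAnnotationTable:
    """Read a two-column TSV: protein_id, comma-joined 1-based positions.

    Lines starting with '#' are comments.  Duplicate positions are
    dropped; the result is sorted.
    """
    path = Path(path)
    table: SiteAnnotationTable = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, "
                    f"got {len(parts)}"
                )
            pid, pos_field = parts[0].strip(), parts[1].strip()
            positions = set()
            for tok in pos_field.split(","):
                tok = tok.strip()
                try:
                    p = int(tok)
                except ValueError as exc:
                    raise FormatError(
                        f"{path}:{lineno}: non-integer position {tok!r}"
                    ) from exc
                if p <= 0:
                    raise FormatError(
                        f"{path}:{lineno}: position {p} is not 1-based"
                    )
                positions.add(p)
            table.setdefault(pid, [])
            table[pid] = sorted(set(table[pid]) | positions)
    return table


def write_site_annotations(table: Mapping[str, Iterable[int]], path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# protein_id\tpositions (1-based, comma-separated)\n")
        for pid in sorted(table):
            fh.write(f"{pid}\t{','.join(str(p) for p in sorted(set(table[pid])))}\n")


def attach_annotations(
    records: Sequence[ProteinRecord], table: SiteAnnotationTable
) -> List[ProteinRecord]:
    """Return new records with binding positions from ``table`` attached.

    Every annotated id must resolve against the records, and every
    position must fall inside its sequence.
    """
    by_id = {r.id: r for r in records}
    missing = sorted(set(table) - set(by_id))
    if missing:
        raise ConsistencyError(
            f"annotated protein id(s) not present in FASTA: {missing}"
        )
    out = []
    for rec in records:
        positions = set(table.get(rec.id, ()))
        out.append(ProteinRecord(rec.id, rec.sequence, positions))
    return out


# ---------------------------------------------------------------------------
# Predictions


PREDICTION_HEADER = "protein_id\tposition\tscore\tlabel"


def write_predictions(records: Iterable[PredictionRecord], path) -> None:
    """Write predictions as TSV; scores printed with 6 decimal places."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(PREDICTION_HEADER + "\n")
        for rec in records:
            fh.write(
                f"{rec.protein_id}\t{rec.position}\t{rec.score:.6f}\t{rec.label}\n"
            )


def read_predictions(path) -> List[PredictionRecord]:
    path = Path(path)
    out: List[PredictionRecord] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        if header != PREDICTION_HEADER:
            raise FormatError(f"{path}: unexpected header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            out.append(
                PredictionRecord(
                    protein_id=parts[0],
                    position=int(parts[1]),
                    score=float(parts[2]),
                    label=int(parts[3]),
                )
            )
    return out
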