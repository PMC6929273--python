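"""PSI-BLAST ASCII PSSM reading/writing and per-protein evolution matrices.

A PSSM is the L x 20 log-odds profile PSI-BLAST emits with
``-out_ascii_pssm`` (one protein per file).  The per-protein descriptor used
downstream is the 20 x 20 "evolution matrix" M'M, which is symmetric positive
semidefinite by construction and independent of sequence length, so proteins
of different lengths become comparable fixed-size samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "PSSMFormatError",
    "ScoreMatrix",
    "EvolutionMatrix",
    "parse_pssm",
    "write_pssm",
    "evolution_matrix",
    "filter_short_sequences",
]

logger = logging.getLogger(__name__)

#: Fixed PSI-BLAST column order of the 20 standard amino acids.
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

#: Default minimum sequence length retained when building datasets; shorter
#: records are treated as fragments.
MIN_SEQUENCE_LENGTH = 50


class PSSMFormatError(ValueError):
    """Raised when ASCII PSSM content cannot be parsed."""


@dataclass
class ScoreMatrix:
    """An L x 20 integer log-odds profile for one protein.

    Attributes
    ----------
    protein_id : str
        Identifier of the profiled protein.
    scores : numpy.ndarray
        Integer array of shape (L, 20); rows are sequence positions, columns
        follow :data:`AMINO_ACIDS` order.
    residues : str
        The length-L query sequence (one-letter codes, as printed in the
        PSSM body).
    """

    protein_id: str
    scores: np.ndarray
    residues: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(
                f"scores must be L x 20, got shape {self.scores.shape}"
            )
        if self.scores.shape[0] < 1:
            raise ValueError("scores must have at least one row")
        if not np.issubdtype(self.scores.dtype, np.integer):
            if not np.array_equal(self.scores, np.round(self.scores)):
                raise ValueError("log-odds scores must be integers")
            self.scores = self.scores.astype(np.int64)
        if len(self.residues) != self.scores.shape[0]:
            raise ValueError(
                f"residue string length {len(self.residues)} does not match "
                f"matrix rows {self.scores.shape[0]}"
            )

    @property
    def length(self) -> int:
        return self.scores.shape[0]


@dataclass
class EvolutionMatrix:
    """The 20 x 20 transpose-product M'M of a protein's score matrix."""

    protein_id: str
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (20, 20):
            raise ValueError(f"expected 20 x 20 matrix, got {self.values.shape}")


def parse_pssm(text: str, protein_id: str = "") -> ScoreMatrix:
    """Parse PSI-BLAST ``-out_ascii_pssm`` content into a :class:`ScoreMatrix`.

    Body rows are recognised by shape — an integer position index, a residue
    letter, then at least 20 integer fields — rather than by line number, so
    header/footer variations across PSI-BLAST versions are tolerated.  Only
    the first 20 numeric columns (the log-odds block) are kept; the weighted
    percentage block and trailing per-row statistics are ignored.

    Parameters
    ----------
    text : str
        Raw file content.
    protein_id : str, optional
        Identifier to attach to the parsed matrix.

    Raises
    ------
    PSSMFormatError
        If a position row has fewer than 20 numeric fields, a log-odds field
        is not an integer, or the file has no body rows at all.
    """
    rows: list[list[int]] = []
    residues: list[str] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        tokens = line.split()
        if len(tokens) < 3:
            continue
        if not tokens[0].lstrip("-").isdigit():
            continue  # header, axis-label or footer line
        if not (len(tokens[1]) == 1 and tokens[1].isalpha()):
            continue
        fields = tokens[2:]
        numeric: list[str] = []
        for tok in fields:
            # the trailing statistics columns are floats; stop there
            try:
                int(tok)
            except ValueError:
                break
            numeric.append(tok)
        if len(numeric) < 20:
            raise PSSMFormatError(
                f"line {lineno}: position row has {len(numeric)} numeric "
                "fields, expected at least 20 integer log-odds"
            )
        rows.append([int(t) for t in numeric[:20]])
        residues.append(tokens[1].upper())
    if not rows:
        raise PSSMFormatError("no PSSM body rows found (empty body)")
    return ScoreMatrix(
        protein_id=protein_id,
        scores=np.array(rows, dtype=np.int64),
        residues="".join(residues),
    )


def write_pssm(m: ScoreMatrix) -> str:
    """Serialise a :class:`ScoreMatrix` to the ASCII dialect :func:`parse_pssm`
    accepts.  Log-odds integers round-trip bit-exactly; the percentage block
    is written as zeros (it is not carried by :class:`ScoreMatrix`)."""
    header = [
        "",
        "Last position-specific scoring matrix computed, weighted, and scaled",
        "            " + "   ".join(AMINO_ACIDS) + "   " + "   ".join(AMINO_ACIDS),
    ]
    body = []
    for i in range(m.length):
        logodds = " ".join(f"{v:4d}" for v in m.scores[i])
        pct = " ".join(f"{0:4d}" for _ in range(20))
        body.append(f"{i + 1:5d} {m.residues[i]}  {logodds}  {pct}  0.00 0.00")
    footer = ["", "                      K         Lambda", ""]
    return "\n".join(header + body + footer)


def evolution_matrix(m: ScoreMatrix, normalize: str = "none") -> EvolutionMatrix:
    """Compute the 20 x 20 evolution matrix M'M of a score matrix.

    M'M is the only orientation giving a length-independent 20 x 20 result
    (MM' would be L x L).  Scores enter as raw log-odds integers by default;
    ``normalize='sigmoid'`` first maps each score through the logistic
    function 1/(1+exp(-x)) for users following that convention.
    """
    if normalize == "none":
        mat = m.scores.astype(float)
    elif normalize == "sigmoid":
        mat = 1.0 / (1.0 + np.exp(-m.scores.astype(float)))
    else:
        raise ValueError(f"unknown normalize mode {normalize!r}")
    return EvolutionMatrix(protein_id=m.protein_id, values=mat.T @ mat)


def filter_short_sequences(
    records: list[tuple[str, str]], min_len: int = MIN_SEQUENCE_LENGTH
) -> list[tuple[str, str]]:
    """Drop sequences shorter than ``min_len`` residues (fragment removal).

    Order is preserved.  Empty sequences count as length 0 and are dropped
    with a logged warning.
    """
    kept = []
    for pid, seq in records:
        if not seq:
            logger.warning("dropping %s: empty sequence", pid)
            continue
        if len(seq) >= min_len:
            kept.append((pid, seq))
    return kept
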