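"""Per-column evolutionary conservation from a protein MSA.

The default metric is normalized Shannon information, 1 - H/log2(20), where H
is the entropy of the amino-acid frequencies in a column with gaps excluded.
A fully unanimous column scores 1.0; a column where all twenty amino acids
appear equally scores 0.0.  Scores are mapped onto query residue numbers by
walking the query row's non-gap positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError

GAP_CHARS = frozenset("-.")
ALPHABET_SIZE = 20  # standard amino acids
LOW_COVERAGE = 0.5  # columns below this non-gap fraction are flagged


@dataclass
class Msa:
    """A protein multiple sequence alignment (equal-length rows)."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise AlignmentError("empty alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment: row lengths {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"sequence id {seq_id!r} not in alignment") from None


@dataclass
class ConservationTrack:
    """Per query-residue conservation score in [0, 1] with column coverage."""

    scores: dict[int, float]
    coverage: dict[int, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "residue": res,
                "score": self.scores[res],
                "coverage": self.coverage[res],
                "low_confidence": self.coverage[res] < LOW_COVERAGE,
            }
            for res in sorted(self.scores)
        ]
        return pd.DataFrame(rows)


def read_alignment(path: str | Path, format: str = "fasta") -> Msa:
    """Read an aligned FASTA file; ragged alignments are rejected."""
    try:
        records = list(SeqIO.parse(str(path), format))
    except (ValueError, OSError) as exc:
        raise AlignmentError(f"cannot read alignment {path}: {exc}") from exc
    if not records:
        raise AlignmentError(f"{path}: no sequences found")
    msa = Msa(ids=[r.id for r in records], rows=[str(r.seq).upper() for r in records])
    return msa


def write_alignment(msa: Msa, path: str | Path, format: str = "fasta") -> None:
    records = [
        SeqRecord(Seq(row), id=seq_id, description="") for seq_id, row in zip(msa.ids, msa.rows)
    ]
    AlignIO.write(AlignIO.MultipleSeqAlignment(records), str(path), format)


def column_entropy_score(symbols: str) -> tuple[float, float]:
    """(score, coverage) for one column; gaps excluded from frequencies."""
    residues = [s for s in symbols if s not in GAP_CHARS]
    coverage = len(residues) / len(symbols) if symbols else 0.0
    if not residues:
        return 0.0, 0.0
    _, counts = np.unique(np.array(residues), return_counts=True)
    freqs = counts / counts.sum()
    entropy = float(-np.sum(freqs * np.log2(freqs)))
    score = 1.0 - entropy / np.log2(ALPHABET_SIZE)
    return float(np.clip(score, 0.0, 1.0)), coverage


def column_conservation(msa: Msa) -> list[float]:
    """Normalized Shannon-information score for every alignment column."""
    if msa.n_sequences < 2:
        raise AlignmentError("column_conservation needs >= 2 sequences")
    return [
        column_entropy_score("".join(row[col] for row in msa.rows))[0]
        for col in range(msa.length)
    ]


def map_to_query(msa: Msa, query_id: str, query_start_number: int = 1) -> ConservationTrack:
    """Map column scores onto query residue numbers.

    Columns where the query row carries a gap are skipped; residue numbers
    increase by one over the query's non-gap positions, starting at
    ``query_start_number``.
    """
    query = msa.row(query_id)
    scores: dict[int, float] = {}
    coverage: dict[int, float] = {}
    resnum = query_start_number
    for col in range(msa.length):
        if query[col] in GAP_CHARS:
            continue
        column = "".join(row[col] for row in msa.rows)
        score, cov = column_entropy_score(column)
        scores[resnum] = score
        coverage[resnum] = cov
        resnum += 1
    return ConservationTrack(scores=scores, coverage=coverage)
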