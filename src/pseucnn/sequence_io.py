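"""Reading, validating and writing labeled RNA sequence windows.

Inputs to the predictor are center-aligned, fixed-length RNA windows with a
uridine at the central position: one FASTA file of pseudouridine-positive
windows and one of negatives, or a single labeled TSV. DNA-alphabet files
(T instead of U) are accepted and silently normalized, since benchmark data
in this field are frequently distributed as DNA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")


class FastaParseError(ValueError):
    """A FASTA file could not be parsed; the message names the record."""


class SequenceValidationError(ValueError):
    """A residue outside {A, C, G, U} survived normalization."""


@dataclass(frozen=True)
class RnaSequence:
    """A single RNA window: an identifier plus residues over {A, C, G, U}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 2:
            raise SequenceValidationError(
                f"sequence {self.id!r}: length {len(self.residues)} < 2 "
                "(at least one dinucleotide is required)"
            )
        for pos, res in enumerate(self.residues, start=1):
            if res not in RNA_ALPHABET:
                raise SequenceValidationError(
                    f"sequence {self.id!r}: invalid residue {res!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)


def normalize_residues(raw: str) -> str:
    """Uppercase and map the DNA letter T to the RNA letter U."""
    return raw.upper().replace("T", "U")


@dataclass
class LabeledSequenceSet:
    """An ordered collection of RNA windows with binary Ψ/non-Ψ labels.

    ``labels[i] == 1`` marks ``sequences[i]`` as a pseudouridine site.
    Class balance is a property of particular datasets, not of this container.
    """

    sequences: list[RnaSequence]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.sequences) != len(self.labels):
            raise ValueError(
                f"{len(self.sequences)} sequences but {len(self.labels)} labels"
            )
        bad = set(np.unique(self.labels)) - {0, 1}
        if bad:
            raise ValueError(f"labels must be binary; found {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(zip(self.sequences, self.labels))

    @property
    def max_length(self) -> int:
        return max(len(s) for s in self.sequences)


def read_fasta(path: str | Path) -> list[RnaSequence]:
    """Read all records of a FASTA file as validated RNA sequences.

    Lowercase letters are uppercased and T is mapped to U before validation;
    any other letter raises :class:`SequenceValidationError` with its position.
    """
    path = Path(path)
    records = []
    mapped_t = False
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            raw = str(rec.seq)
            if not raw:
                raise FastaParseError(f"{path}: record {rec.id!r} has an empty sequence")
            if "T" in raw or "t" in raw:
                mapped_t = True
            records.append(RnaSequence(id=rec.id, residues=normalize_residues(raw)))
    except SequenceValidationError:
        raise
    except FastaParseError:
        raise
    except ValueError as exc:  # biopython parse failure
        raise FastaParseError(f"{path}: malformed FASTA ({exc})") from exc
    if mapped_t:
        logger.info("%s: T residues normalized to U (DNA alphabet accepted)", path)
    return records


def write_fasta(sequences: Iterable[RnaSequence], path: str | Path) -> None:
    """Write sequences as unwrapped FASTA, preserving order and ids."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for seq in sequences:
            fh.write(f">{seq.id}\n{seq.residues}\n")


def load_dataset(pos_path: str | Path, neg_path: str | Path) -> LabeledSequenceSet:
    """Build a labeled set from a positive and a negative FASTA file.

    Positives (label 1) come first in the returned set, then negatives
    (label 0); labels are determined solely by which file a record is in.
    """
    pos = read_fasta(pos_path)
    neg = read_fasta(neg_path)
    if not pos:
        raise FastaParseError(f"{pos_path}: no FASTA records found")
    if not neg:
        raise FastaParseError(f"{neg_path}: no FASTA records found")
    labels = np.concatenate([np.ones(len(pos), dtype=int), np.zeros(len(neg), dtype=int)])
    return LabeledSequenceSet(sequences=pos + neg, labels=labels)


def load_tsv(path: str | Path) -> LabeledSequenceSet:
    """Load a single-file dataset: TSV with columns id, sequence, label."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "sequence": str})
    missing = {"id", "sequence", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing TSV columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{path}: no rows")
    seqs = [
        RnaSequence(id=row.id, residues=normalize_residues(row.sequence))
        for row in df.itertuples(index=False)
    ]
    return LabeledSequenceSet(sequences=seqs, labels=df["label"].to_numpy())


def write_tsv(sset: LabeledSequenceSet, path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": [s.id for s in sset.sequences],
            "sequence": [s.residues for s in sset.sequences],
            "label": sset.labels,
        }
    ).to_csv(path, sep="\t", index=False)


@dataclass
class CenterUridineReport:
    """Result of the central-uridine sanity check (warning-level, not a filter)."""

    violations: list[str] = field(default_factory=list)
    unverifiable: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations and not self.unverifiable


def check_center_uridine(sset: LabeledSequenceSet) -> CenterUridineReport:
    """Report ids whose central residue is not U.

    The center of an odd-length window of length N is index (N-1)/2.
    Even-length windows have no well-defined center and are reported as
    unverifiable rather than rejected: the feature pipeline itself works
    for any length ≥ 2.
    """
    report = CenterUridineReport()
    for seq, _ in sset:
        n = len(seq)
        if n % 2 == 0:
            report.unverifiable.append(seq.id)
        elif seq.residues[(n - 1) // 2] != "U":
            report.violations.append(seq.id)
    if report.violations:
        logger.warning("central residue is not U for %d sequence(s)", len(report.violations))
    return report
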