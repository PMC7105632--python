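"""FASTA and label-file input/output with strict alphabet validation.

Sequences are validated against the 20 standard amino acids after
uppercasing; records with non-standard residues (B, J, O, U, X, Z, ``*``,
gaps) are rejected with an explicit error naming the record and the
offending characters, or skipped with a logged warning when
``drop_invalid=True``.  Labels are binary (0/1) and may come from a trailing
``|label`` token in the FASTA header or from a two-column TSV.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .exceptions import FastaParseError, LabelError, PhageHydroError, SequenceValidationError

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetically ordered. This ordering fixes
#: feature-name order everywhere downstream.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(ALPHABET)

__all__ = [
    "ALPHABET",
    "AA_SET",
    "ProteinRecord",
    "Dataset",
    "read_fasta",
    "write_fasta",
    "read_labels",
    "write_labels",
]


@dataclass(frozen=True)
class ProteinRecord:
    """One validated amino-acid sequence with an optional binary label."""

    id: str
    sequence: str
    label: int | None = None

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise SequenceValidationError(f"record id {self.id!r} is empty or contains whitespace")
        object.__setattr__(self, "sequence", self.sequence.upper())
        if len(self.sequence) == 0:
            raise SequenceValidationError(f"record {self.id!r} has an empty sequence")
        bad = sorted({c for c in self.sequence if c not in AA_SET})
        if bad:
            raise SequenceValidationError(
                f"record {self.id!r} contains non-standard residues {''.join(bad)!r}; "
                "only the 20 standard amino acids are accepted"
            )
        if self.label is not None and self.label not in (0, 1):
            raise SequenceValidationError(f"record {self.id!r}: label must be 0 or 1, got {self.label!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Dataset:
    """An ordered collection of :class:`ProteinRecord` with unique ids.

    ``stage_tag`` documents which classification task the labels refer to
    (e.g. ``"enzyme"`` for enzyme vs non-enzyme, ``"hydrolase"`` for
    hydrolase vs other enzyme).
    """

    records: list[ProteinRecord] = field(default_factory=list)
    stage_tag: str = ""

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PhageHydroError(f"duplicate record ids: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> ProteinRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    @property
    def labels(self) -> list[int] | None:
        labs = [r.label for r in self.records]
        if any(l is None for l in labs):
            return None
        return labs  # type: ignore[return-value]

    def require_labels(self) -> list[int]:
        labs = self.labels
        if labs is None:
            missing = [r.id for r in self.records if r.label is None]
            raise LabelError(f"dataset is not fully labelled; unlabelled ids: {missing[:5]}")
        if len(set(labs)) < 2:
            raise LabelError("both classes must be present for training, found only one")
        return labs


def _split_header(header: str, label_from_header: bool) -> tuple[str, int | None]:
    token = header.split()[0] if header.split() else ""
    label: int | None = None
    if label_from_header and "|" in token:
        token, _, raw = token.rpartition("|")
        try:
            label = int(raw)
        except ValueError:
            raise LabelError(f"header label {raw!r} for record {token!r} is not 0/1")
    return token, label


def read_fasta(
    path,
    label_source: str | Path | None = None,
    drop_invalid: bool = False,
    stage_tag: str = "",
) -> Dataset:
    """Read a FASTA file into a validated :class:`Dataset`.

    Parameters
    ----------
    path
        FASTA file; multi-line sequences and lowercase residues are accepted.
    label_source
        ``None`` (no labels), the string ``"header"`` (labels as a trailing
        ``|label`` token on the header id), or a path to a two-column
        ``id<TAB>label`` TSV.
    drop_invalid
        If True, records failing residue validation are skipped with a
        logged warning instead of raising.
    """
    path = Path(path)
    if not path.exists():
        raise FastaParseError(f"{path}: file not found")
    # locate the first non-blank line for a clear malformed-input diagnostic
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno}: expected a '>' header, got {line.strip()[:30]!r}"
                    )
                break
        else:
            logger.warning("%s: empty FASTA file, returning empty dataset", path)
            return Dataset([], stage_tag=stage_tag)

    label_map: dict[str, int] | None = None
    from_header = label_source == "header"
    if label_source is not None and not from_header:
        label_map = read_labels(label_source)

    records: list[ProteinRecord] = []
    with open(path) as handle:
        for header, seq in SimpleFastaParser(handle):
            rid, label = _split_header(header, from_header)
            if not rid:
                raise FastaParseError(f"{path}: record with empty id (header {header!r})")
            if label_map is not None:
                label = label_map.get(rid)
            try:
                records.append(ProteinRecord(rid, seq.replace(" ", ""), label))
            except SequenceValidationError as exc:
                if drop_invalid:
                    logger.warning("skipping invalid record: %s", exc)
                else:
                    raise
    if label_map is not None:
        known = {r.id for r in records}
        unknown = sorted(set(label_map) - known)
        if unknown:
            raise LabelError(f"label file references unknown ids: {unknown[:5]}")
    return Dataset(records, stage_tag=stage_tag)


def write_fasta(dataset: Dataset, path, include_labels: bool = False, width: int = 60) -> None:
    """Write a dataset as FASTA; with ``include_labels`` the header carries ``|label``."""
    with open(path, "w") as out:
        for rec in dataset:
            header = rec.id
            if include_labels and rec.label is not None:
                header = f"{rec.id}|{rec.label}"
            out.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                out.write(rec.sequence[i : i + width] + "\n")


def read_labels(path) -> dict[str, int]:
    """Read a two-column ``id<TAB>label`` TSV into a dict; labels must be 0/1."""
    labels: dict[str, int] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise LabelError(f"{path}: line {lineno}: expected 'id<TAB>label'")
            rid, raw = parts
            if rid in labels:
                raise LabelError(f"{path}: line {lineno}: duplicate id {rid!r}")
            try:
                lab = int(raw)
            except ValueError:
                raise LabelError(f"{path}: line {lineno}: label {raw!r} is not an integer")
            if lab not in (0, 1):
                raise LabelError(f"{path}: line {lineno}: label must be 0 or 1, got {lab}")
            labels[rid] = lab
    return labels


def write_labels(dataset: Dataset, path) -> None:
    with open(path, "w") as out:
        for rec in dataset:
            if rec.label is None:
                raise LabelError(f"record {rec.id!r} has no label to write")
            out.write(f"{rec.id}\t{rec.label}\n")
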