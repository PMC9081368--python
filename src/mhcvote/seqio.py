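"""Protein sequence I/O, sanitization, labels and fold partitions.

Sequences are plain strings over the 20 standard amino-acid letters
(A C D E F G H I K L M N P Q R S T V W Y).  Nonstandard residues
(B, J, O, U, X, Z, gaps, stops, lowercase) are handled by a sanitization
policy: ``"drop"`` (default) uppercases and removes them with a warning,
``"reject"`` raises on the first offending character.

Fold assignment for cross-validation is stratified by class and seeded so
that a run is reproducible from its configuration alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from sklearn.model_selection import StratifiedKFold

from .errors import DataError

logger = logging.getLogger(__name__)

#: The 20 standard amino acids in alphabetical order.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET_SET = frozenset(ALPHABET)

#: Allowed sanitization policies.
POLICIES = ("drop", "reject")


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence: an identifier plus residues over the 20-letter alphabet."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise DataError(f"sequence {self.id!r}: empty residue string")
        bad = set(self.residues) - _ALPHABET_SET
        if bad:
            raise DataError(
                f"sequence {self.id!r}: nonstandard residues {sorted(bad)}; "
                "sanitize before constructing ProteinSequence"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class LabeledDataset:
    """Sequences with aligned binary labels (1 = MHC, 0 = non-MHC)."""

    sequences: list[ProteinSequence]
    labels: list[int]

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.labels):
            raise DataError(
                f"{len(self.sequences)} sequences but {len(self.labels)} labels"
            )
        if any(l not in (0, 1) for l in self.labels):
            raise DataError("labels must be 0 (non-MHC) or 1 (MHC)")
        ids = [s.id for s in self.sequences]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise DataError(f"duplicate sequence IDs: {dup}")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]

    def class_counts(self) -> tuple[int, int]:
        """Return (n_negative, n_positive)."""
        pos = sum(self.labels)
        return len(self.labels) - pos, pos

    def require_two_classes(self) -> None:
        neg, pos = self.class_counts()
        if neg == 0 or pos == 0:
            raise DataError(
                f"training requires both classes; got {pos} positives, {neg} negatives"
            )


@dataclass
class FoldAssignment:
    """A stratified partition of dataset indices into ``n_folds`` folds."""

    n_folds: int
    fold_of: np.ndarray  # per-sequence fold index in [0, n_folds)

    def indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)


def sanitize(residues: str, policy: str = "drop") -> str:
    """Uppercase ``residues`` and apply the nonstandard-character policy.

    Idempotent: sanitizing an already-clean string is the identity.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    upper = residues.upper()
    if policy == "reject":
        bad = set(upper) - _ALPHABET_SET
        if bad:
            raise DataError(f"nonstandard residues {sorted(bad)} under 'reject' policy")
        return upper
    return "".join(c for c in upper if c in _ALPHABET_SET)


def read_fasta(path: str | Path, policy: str = "drop") -> list[ProteinSequence]:
    """Read a FASTA file into sanitized :class:`ProteinSequence` records.

    IDs are the first whitespace-delimited token of each header. Records whose
    residues are empty after sanitization are skipped with a warning; duplicate
    IDs raise :class:`DataError`.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"FASTA file not found: {path}")
    out: list[ProteinSequence] = []
    seen: set[str] = set()
    skipped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DataError(f"duplicate sequence ID {rec.id!r} in {path}")
        seen.add(rec.id)
        clean = sanitize(str(rec.seq), policy)
        if not clean:
            skipped += 1
            logger.warning(
                "record %r in %s empty after sanitization; skipped", rec.id, path
            )
            continue
        if clean != str(rec.seq):
            logger.warning(
                "record %r: removed %d nonstandard/lowercase characters",
                rec.id,
                len(rec.seq) - len(clean),
            )
        out.append(ProteinSequence(id=rec.id, residues=clean))
    if skipped:
        logger.warning("%s: skipped %d record(s) with no standard residues", path, skipped)
    return out


def write_fasta(sequences: Iterable[ProteinSequence], path: str | Path) -> None:
    """Write sequences as FASTA, wrapped at 60 columns."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


def load_labeled(
    pos_path: str | Path, neg_path: str | Path, policy: str = "drop"
) -> LabeledDataset:
    """Load a two-FASTA dataset: positives (label 1) then negatives (label 0)."""
    pos = read_fasta(pos_path, policy)
    neg = read_fasta(neg_path, policy)
    overlap = {s.id for s in pos} & {s.id for s in neg}
    if overlap:
        raise DataError(f"IDs present in both files: {sorted(overlap)}")
    return LabeledDataset(
        sequences=pos + neg, labels=[1] * len(pos) + [0] * len(neg)
    )


def read_label_tsv(path: str | Path) -> dict[str, int]:
    """Read an ``id<TAB>label`` table (labels in {0,1}; optional header)."""
    mapping: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DataError(f"{path}:{lineno}: expected 2 tab-separated columns")
            sid, lab = parts
            if lineno == 1 and not lab.lstrip("-").isdigit():
                continue  # header row ("id<TAB>label")
            if lab not in ("0", "1"):
                raise DataError(f"{path}:{lineno}: label must be 0 or 1, got {lab!r}")
            if sid in mapping:
                raise DataError(f"{path}:{lineno}: duplicate ID {sid!r}")
            mapping[sid] = int(lab)
    return mapping


def load_labeled_from_table(
    fasta_path: str | Path, table_path: str | Path, policy: str = "drop"
) -> LabeledDataset:
    """Load one FASTA plus an ``id<TAB>label`` table."""
    seqs = read_fasta(fasta_path, policy)
    labels = read_label_tsv(table_path)
    missing = [s.id for s in seqs if s.id not in labels]
    if missing:
        raise DataError(f"IDs missing from label table: {missing[:10]}")
    return LabeledDataset(sequences=seqs, labels=[labels[s.id] for s in seqs])


def stratified_kfold(
    ds: LabeledDataset, n_folds: int, seed: int
) -> FoldAssignment:
    """Assign each sequence to one of ``n_folds`` stratified folds.

    Deterministic for a fixed seed; within each class, fold sizes differ by
    at most one. Each class must have at least ``n_folds`` members.
    """
    if n_folds < 2:
        raise DataError(f"n_folds must be >= 2, got {n_folds}")
    neg, pos = ds.class_counts()
    if min(neg, pos) < n_folds:
        raise DataError(
            f"each class needs >= {n_folds} members for {n_folds}-fold CV; "
            f"got {pos} positives, {neg} negatives"
        )
    y = np.asarray(ds.labels)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_of = np.empty(len(ds), dtype=int)
    for k, (_, test_idx) in enumerate(skf.split(np.zeros(len(ds)), y)):
        fold_of[test_idx] = k
    return FoldAssignment(n_folds=n_folds, fold_of=fold_of)
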