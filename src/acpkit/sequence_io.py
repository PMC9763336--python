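"""Peptide dataset I/O, validation, splitting and redundancy filtering.

Peptides are short amino-acid sequences (3-50 residues over the 20-letter
alphabet), optionally carrying a binary activity label (1 = anticancer
peptide, 0 = non-ACP).  Datasets are read from / written to plain FASTA,
with labels either appended to the record id (``>pep1|1``) or supplied as a
two-column TSV.  Splitting utilities produce class-balanced K-fold and
holdout partitions; :func:`identity_filter` removes test peptides too
similar to a training set, using a global-alignment sequence identity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET_SET = frozenset(ALPHABET)

#: Padded sequence length; also the maximum accepted peptide length.
LMAX = 50
#: Minimum accepted peptide length.
LMIN = 3


class ValidationError(ValueError):
    """A peptide or dataset violates the sequence contract."""


class FastaParseError(ValueError):
    """The input file is not parseable as FASTA."""


@dataclass(frozen=True)
class Peptide:
    """One identified peptide sequence with an optional binary label."""

    id: str
    sequence: str
    label: int | None = None
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)

    def validate(self, lmin: int = LMIN, lmax: int = LMAX) -> "Peptide":
        """Check alphabet and length constraints, returning self.

        Raises
        ------
        ValidationError
            If the sequence is empty, contains a residue outside the
            20-letter alphabet, or its length falls outside [lmin, lmax].
        """
        if not self.sequence:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        bad = sorted(set(self.sequence) - ALPHABET_SET)
        if bad:
            raise ValidationError(
                f"record {self.id!r}: illegal residue character(s) "
                f"{', '.join(repr(c) for c in bad)}"
            )
        if not lmin <= len(self.sequence) <= lmax:
            raise ValidationError(
                f"record {self.id!r}: length {len(self.sequence)} outside "
                f"[{lmin}, {lmax}]"
            )
        if self.label is not None and self.label not in (0, 1):
            raise ValidationError(f"record {self.id!r}: label must be 0 or 1")
        return self


@dataclass
class PeptideDataset:
    """An ordered collection of peptides with unique ids."""

    peptides: list[Peptide] = field(default_factory=list)
    name: str = "dataset"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p in self.peptides:
            if p.id in seen:
                raise ValidationError(f"duplicate peptide id {p.id!r}")
            seen.add(p.id)

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self) -> Iterator[Peptide]:
        return iter(self.peptides)

    def __getitem__(self, key: int | str) -> Peptide:
        if isinstance(key, str):
            for p in self.peptides:
                if p.id == key:
                    return p
            raise KeyError(key)
        return self.peptides[key]

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.peptides]

    @property
    def labels(self) -> np.ndarray:
        """Label vector; raises if any peptide is unlabeled."""
        if any(p.label is None for p in self.peptides):
            raise ValidationError(f"dataset {self.name!r} has unlabeled peptides")
        return np.array([p.label for p in self.peptides], dtype=int)

    def validate(self, lmin: int = LMIN, lmax: int = LMAX) -> "PeptideDataset":
        for p in self.peptides:
            p.validate(lmin=lmin, lmax=lmax)
        return self

    def subset(self, ids: Iterable[str], name: str | None = None) -> "PeptideDataset":
        wanted = set(ids)
        return PeptideDataset(
            [p for p in self.peptides if p.id in wanted],
            name=name or self.name,
        )

    def with_labels(self, labels: Mapping[str, int]) -> "PeptideDataset":
        """Attach labels from an id -> {0,1} mapping."""
        missing = [p.id for p in self.peptides if p.id not in labels]
        if missing:
            raise ValidationError(f"no label for ids: {missing[:5]}")
        return PeptideDataset(
            [replace(p, label=int(labels[p.id])) for p in self.peptides],
            name=self.name,
        )

    def class_counts(self) -> tuple[int, int]:
        y = self.labels
        return int((y == 1).sum()), int((y == 0).sum())


@dataclass(frozen=True)
class SplitSpec:
    """A K-fold assignment of labeled peptides, class-balanced per fold."""

    fold_assignments: dict[str, int]
    K: int
    seed: int

    def fold_ids(self, k: int) -> list[str]:
        return [i for i, f in self.fold_assignments.items() if f == k]


# ---------------------------------------------------------------------------
# FASTA / label I/O
# ---------------------------------------------------------------------------

def _split_header_label(record_id: str) -> tuple[str, int | None]:
    if "|" in record_id:
        base, _, suffix = record_id.rpartition("|")
        if suffix in ("0", "1"):
            return base, int(suffix)
    return record_id, None


def read_fasta(
    path: str | Path,
    validate: bool = True,
    parse_header_labels: bool = True,
) -> PeptideDataset:
    """Read peptides from a FASTA file.

    Sequences are uppercased and record order preserved.  A record id
    ending in ``|1`` or ``|0`` is interpreted as carrying its label (when
    `parse_header_labels`).  An empty file yields an empty dataset with a
    logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # SeqIO silently yields nothing for leading junk; pre-check the framing
    # so malformed input fails loudly with a line number.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: expected FASTA header '>', "
                    f"got {line.strip()[:30]!r}"
                )
            break
    peptides = []
    for record in SeqIO.parse(str(path), "fasta"):
        rid, label = (
            _split_header_label(record.id)
            if parse_header_labels
            else (record.id, None)
        )
        desc = record.description.partition(" ")[2]
        peptides.append(Peptide(rid, str(record.seq), label=label, description=desc))
    if not peptides:
        logger.warning("FASTA file %s contains no records", path)
        warnings.warn(f"FASTA file {path} contains no records", stacklevel=2)
    ds = PeptideDataset(peptides, name=path.stem)
    if validate:
        ds.validate()
    return ds


def write_fasta(
    dataset: PeptideDataset, path: str | Path, include_labels: bool = True
) -> None:
    """Write a dataset to FASTA, encoding labels as an ``|label`` id suffix."""
    with open(path, "w") as fh:
        for p in dataset:
            header = p.id
            if include_labels and p.label is not None:
                header = f"{p.id}|{p.label}"
            if p.description:
                header = f"{header} {p.description}"
            fh.write(f">{header}\n{p.sequence}\n")


def read_labels_tsv(path: str | Path) -> dict[str, int]:
    """Read an id -> label mapping from a headerless two-column TSV."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "label"], dtype=str)
    try:
        return {str(r.id): int(r.label) for r in df.itertuples()}
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: labels must be 0/1 integers: {exc}") from exc


def write_labels_tsv(dataset: PeptideDataset, path: str | Path) -> None:
    pd.DataFrame({"id": dataset.ids, "label": dataset.labels}).to_csv(
        path, sep="\t", header=False, index=False
    )


def write_split_tsv(split: SplitSpec, path: str | Path) -> None:
    pd.DataFrame(
        {"id": list(split.fold_assignments), "fold": list(split.fold_assignments.values())}
    ).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def _class_ids(dataset: PeptideDataset) -> tuple[list[str], list[str]]:
    pos, neg = [], []
    for p in dataset:
        if p.label is None:
            raise ValidationError(f"peptide {p.id!r} is unlabeled")
        (pos if p.label == 1 else neg).append(p.id)
    return pos, neg


def stratified_kfold(dataset: PeptideDataset, K: int = 5, seed: int = 0) -> SplitSpec:
    """Deal labeled peptides into K folds, balancing both classes per fold.

    Each class is shuffled with a seeded generator and dealt round-robin,
    so per-class fold sizes differ by at most one.
    """
    if K < 2:
        raise ValueError(f"K must be >= 2, got {K}")
    pos, neg = _class_ids(dataset)
    for ids, cname in ((pos, "positive"), (neg, "negative")):
        if len(ids) < K:
            raise ValueError(
                f"{cname} class has {len(ids)} members, fewer than K={K}"
            )
    rng = np.random.default_rng(seed)
    assignments: dict[str, int] = {}
    for ids in (pos, neg):
        order = rng.permutation(len(ids))
        for rank, idx in enumerate(order):
            assignments[ids[idx]] = rank % K
    # preserve dataset order in the mapping
    assignments = {p.id: assignments[p.id] for p in dataset}
    return SplitSpec(assignments, K=K, seed=seed)


def holdout_split(
    dataset: PeptideDataset, test_fraction: float, seed: int = 0
) -> tuple[PeptideDataset, PeptideDataset]:
    """Stratified train/test split; round(test_fraction * class size) per class."""
    if not 0 < test_fraction < 1:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    pos, neg = _class_ids(dataset)
    if not pos or not neg:
        raise ValueError("both classes must be non-empty")
    rng = np.random.default_rng(seed)
    test_ids: set[str] = set()
    for ids in (pos, neg):
        n_test = round(test_fraction * len(ids))
        order = rng.permutation(len(ids))
        test_ids.update(ids[i] for i in order[:n_test])
    train = dataset.subset(
        [i for i in dataset.ids if i not in test_ids], name=f"{dataset.name}_train"
    )
    test = dataset.subset(test_ids, name=f"{dataset.name}_test")
    return train, test


# ---------------------------------------------------------------------------
# Sequence-identity redundancy filter
# ---------------------------------------------------------------------------

_GAP = -1.0


def _global_align_identity(a: str, b: str) -> float:
    """Identity fraction of an optimal global alignment of `a` and `b`.

    Needleman-Wunsch with match=1, mismatch=0, gap=-1; traceback ties
    broken diagonal-first, then up, then left.  Identity is the number of
    identical aligned positions divided by the shorter sequence length.
    This is a documented stand-in convention, not bit-compatible with
    CD-HIT's greedy clustering identity.
    """
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1))
    score[:, 0] = _GAP * np.arange(n + 1)
    score[0, :] = _GAP * np.arange(m + 1)
    for i in range(1, n + 1):
        ai = a[i - 1]
        row, prev = score[i], score[i - 1]
        for j in range(1, m + 1):
            diag = prev[j - 1] + (1.0 if ai == b[j - 1] else 0.0)
            row[j] = max(diag, prev[j] + _GAP, row[j - 1] + _GAP)
    # traceback, diagonal-first on ties
    i, j, ident = n, m, 0
    while i > 0 and j > 0:
        match = 1.0 if a[i - 1] == b[j - 1] else 0.0
        if score[i, j] == score[i - 1, j - 1] + match:
            ident += int(match)
            i, j = i - 1, j - 1
        elif score[i, j] == score[i - 1, j] + _GAP:
            i -= 1
        else:
            j -= 1
    return ident / min(n, m)


def pairwise_identity(a: str, b: str) -> float:
    """Public wrapper for the global-alignment identity of two sequences."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    return _global_align_identity(a, b)


def identity_filter(
    test: PeptideDataset,
    train: PeptideDataset,
    threshold: float,
) -> PeptideDataset:
    """Keep test peptides whose max identity to any training peptide < threshold.

    Used to build non-redundant test sets at identity thresholds such as
    0.4 / 0.8 / 0.9 for measuring generalization.  An empty result is valid.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    kept = []
    train_seqs = [p.sequence for p in train]
    for p in test:
        if all(_global_align_identity(p.sequence, t) < threshold for t in train_seqs):
            kept.append(p)
    return PeptideDataset(kept, name=f"{test.name}_id{int(threshold * 100)}")
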