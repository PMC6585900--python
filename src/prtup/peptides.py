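"""Peptide records, FASTA I/O and benchmark-dataset assembly.

Datasets of phage-displayed peptides (canonically 7-mers from the Ph.D.-7
library) are read from FASTA, validated against the 20-letter amino-acid
alphabet, de-redundified by a Hamming-distance rule and balanced into a
two-class benchmark of fast-growing (positive) versus regular-growing
(negative) clones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 standard residues in alphabetical single-letter order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)
#: Residue -> index in alphabetical order.
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

POSITIVE_LABEL = 1
NEGATIVE_LABEL = 0


class PeptideError(ValueError):
    """Raised for invalid peptide sequences or malformed datasets."""


@dataclass(frozen=True)
class Peptide:
    """A validated amino-acid sequence with a free-text identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise PeptideError(f"record {self.id!r}: empty sequence")
        bad = next((c for c in seq if c not in _AA_SET), None)
        if bad is not None:
            raise PeptideError(
                f"record {self.id!r}: invalid residue {bad!r} "
                f"(allowed: {AMINO_ACIDS})"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class LabeledDataset:
    """Parallel peptides and binary labels (1 = fast-growing / positive).

    ``provenance`` records how the dataset was built (source files,
    pre/post-filter counts, subsampling seed) so a benchmark can be
    reconstructed exactly.
    """

    peptides: list[Peptide]
    labels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.peptides) != len(self.labels):
            raise PeptideError(
                f"{len(self.peptides)} peptides but {len(self.labels)} labels"
            )
        pos = {p.sequence for p, y in zip(self.peptides, self.labels) if y == POSITIVE_LABEL}
        neg = {p.sequence for p, y in zip(self.peptides, self.labels) if y == NEGATIVE_LABEL}
        overlap = pos & neg
        if overlap:
            raise PeptideError(
                "sequences present in both classes: " + ", ".join(sorted(overlap)[:10])
            )

    def __len__(self) -> int:
        return len(self.peptides)

    @property
    def sequences(self) -> list[str]:
        return [p.sequence for p in self.peptides]

    @property
    def n_positive(self) -> int:
        return int(np.sum(self.labels == POSITIVE_LABEL))

    @property
    def n_negative(self) -> int:
        return int(np.sum(self.labels == NEGATIVE_LABEL))


def read_fasta(path: str | Path, strict: bool = True) -> list[Peptide]:
    """Read peptides from a FASTA file in record order.

    In strict mode the first record failing validation (e.g. an ambiguous
    residue such as X, B or Z) raises :class:`PeptideError`. In lenient
    mode invalid records are skipped; the skip count is logged.
    """
    path = Path(path)
    peptides: list[Peptide] = []
    n_skipped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            peptides.append(Peptide(rec.id, str(rec.seq)))
        except PeptideError:
            if strict:
                raise
            n_skipped += 1
    if n_skipped:
        logger.warning("%s: skipped %d invalid record(s)", path, n_skipped)
    if not peptides and n_skipped == 0:
        logger.warning("%s: no FASTA records found", path)
    return peptides


def iter_fasta(path: str | Path, strict: bool = False) -> Iterator[Peptide | tuple[str, str]]:
    """Stream peptides from FASTA without loading the whole file.

    In lenient mode invalid records are yielded as ``(record_id, error)``
    tuples so callers can report per-record failures while continuing.
    """
    for rec in SeqIO.parse(str(Path(path)), "fasta"):
        try:
            yield Peptide(rec.id, str(rec.seq))
        except PeptideError as exc:
            if strict:
                raise
            yield (rec.id, str(exc))


def write_fasta(peptides: Iterable[Peptide], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.id, description="") for p in peptides
    ]
    SeqIO.write(records, str(Path(path)), "fasta")


def hamming_distance(a: Peptide | str, b: Peptide | str) -> int:
    """Substitution count between two equal-length sequences."""
    sa = a.sequence if isinstance(a, Peptide) else a
    sb = b.sequence if isinstance(b, Peptide) else b
    if len(sa) != len(sb):
        raise PeptideError(
            f"Hamming distance undefined for lengths {len(sa)} and {len(sb)}"
        )
    return sum(x != y for x, y in zip(sa, sb))


def filter_dataset(peptides: Sequence[Peptide], h: int = 2) -> list[Peptide]:
    """Greedy Hamming-distance redundancy filter.

    A peptide is kept iff its distance to every previously kept peptide
    exceeds ``h`` ("within h" — distance 0..h — triggers removal). The pass
    runs in input order, so the first member of any close group survives;
    output order equals input order. Idempotent.
    """
    if h < 0:
        raise ValueError("h must be >= 0")
    if not peptides:
        return []
    length = len(peptides[0])
    if any(len(p) != length for p in peptides):
        raise PeptideError("all peptides must have equal length for filtering")

    # Integer residue matrix of kept peptides: one vectorised comparison
    # against all kept rows per candidate instead of a Python double loop.
    kept: list[Peptide] = []
    kept_mat = np.empty((0, length), dtype=np.int8)
    for p in peptides:
        row = np.frombuffer(p.sequence.encode("ascii"), dtype=np.int8)
        if kept_mat.shape[0]:
            dists = (kept_mat != row).sum(axis=1)
            if int(dists.min()) <= h:
                continue
        kept.append(p)
        kept_mat = np.vstack([kept_mat, row])
    return kept


def assemble_dataset(
    positives: Sequence[Peptide],
    negatives: Sequence[Peptide],
    balance_seed: int = 0,
) -> LabeledDataset:
    """Build a balanced two-class benchmark.

    If negatives outnumber positives they are subsampled without
    replacement (seeded) to match the positive count; class disjointness
    is enforced. Counts before/after are recorded in provenance.
    """
    if not positives or not negatives:
        raise PeptideError("both classes must be non-empty")
    n_neg_before = len(negatives)
    negatives = list(negatives)
    if len(negatives) > len(positives):
        rng = np.random.default_rng(balance_seed)
        idx = rng.choice(len(negatives), size=len(positives), replace=False)
        negatives = [negatives[i] for i in sorted(idx)]
    peptides = list(positives) + negatives
    labels = np.concatenate(
        [np.ones(len(positives), dtype=int), np.zeros(len(negatives), dtype=int)]
    )
    pos_seqs = {p.sequence for p in positives}
    neg_seqs = {p.sequence for p in negatives}
    overlap = pos_seqs & neg_seqs
    if overlap:
        raise PeptideError(
            "sequences present in both classes: " + ", ".join(sorted(overlap)[:10])
        )
    return LabeledDataset(
        peptides,
        labels,
        provenance={
            "n_positive": len(positives),
            "n_negative_before_subsample": n_neg_before,
            "n_negative": len(negatives),
            "balance_seed": balance_seed,
        },
    )


def write_manifest(dataset: LabeledDataset, path: str | Path, source: str = "") -> None:
    """TSV manifest: id, sequence, label, source."""
    with open(path, "w") as fh:
        fh.write("id\tsequence\tlabel\tsource\n")
        for p, y in zip(dataset.peptides, dataset.labels):
            lab = "positive" if y == POSITIVE_LABEL else "negative"
            fh.write(f"{p.id}\t{p.sequence}\t{lab}\t{source}\n")
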