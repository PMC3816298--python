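"""Motif occurrence counting and coverage-proportion profiles.

The statistic profiled for every motif m in a sequence fragment S is

    proportion(m in S) = count(m) * |m| / |S|

i.e. the fraction of the fragment covered by (by default, non-overlapping)
copies of the motif. Proportions rather than raw frequencies are used because
each spectrum set is only a small slice of the 4^6 possible length-6 words.
One proportion per set member, in the set's fixed lexicographic column order,
forms the profile vector handed to clustering.

Counting is on the forward strand only. Every spectrum set is closed under
reverse complement (its composition is self-complementary), so the reverse
strand's signal is partially captured by the complementary columns; no strand
merging is performed and each orientation is a separate column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .spectrum_sets import SpectrumSet, _validate_motif

logger = logging.getLogger(__name__)

#: Contig length below which results may be unreliable; a log warning is
#: emitted for anything shorter. 700 bp fragments were often sufficient in
#: practice, but at least 1000 bp is recommended.
WARN_LENGTH = 700
RECOMMENDED_LENGTH = 1000

COUNT_MODES = ("nonoverlapping", "overlapping")


@dataclass
class SequenceRecord:
    """A read, contig, chromosome or genome: id, free-text description, residues.

    Residues are uppercased on construction; IUPAC letters other than ACGT are
    tolerated (they never match a motif but do count toward sequence length).
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")
        self.residues = self.residues.upper()

    def __len__(self) -> int:
        return len(self.residues)


SequenceLike = Union[str, SequenceRecord]


def _residues(sequence: SequenceLike) -> str:
    text = sequence.residues if isinstance(sequence, SequenceRecord) else sequence
    if not text.isupper():
        text = text.upper()
    return text


def count_occurrences(
    motif: str, sequence: SequenceLike, mode: str = "nonoverlapping"
) -> int:
    """Count exact matches of *motif* in *sequence*.

    nonoverlapping (default)
        Left-to-right greedy scan: after a match the scan resumes |motif|
        positions further (no nested/overlapping copies are counted).
    overlapping
        Every matching start position is counted.

    Matching is case-insensitive and exact over ACGT; any other letter (N,
    IUPAC ambiguity codes, ...) in a window breaks the match. A motif longer
    than the sequence yields 0.
    """
    m = _validate_motif(motif)
    if mode not in COUNT_MODES:
        raise ValueError(f"mode must be one of {COUNT_MODES}, got {mode!r}")
    text = _residues(sequence)
    step = len(m) if mode == "nonoverlapping" else 1
    n = 0
    pos = text.find(m)
    while pos != -1:
        n += 1
        pos = text.find(m, pos + step)
    return n


def proportion(motif: str, sequence: SequenceLike, mode: str = "nonoverlapping") -> float:
    """Fraction of the sequence covered by counted copies of the motif."""
    text = _residues(sequence)
    if not text:
        raise ValueError("cannot compute a proportion on an empty sequence")
    m = _validate_motif(motif)
    return count_occurrences(m, text, mode) * len(m) / len(text)


@dataclass
class ProfileVector:
    """Eq.-style coverage proportions of one sequence over one spectrum set."""

    sequence_id: str
    set_name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def profile(
    sequence: SequenceRecord, spectrum_set: SpectrumSet, mode: str = "nonoverlapping"
) -> ProfileVector:
    """Profile one sequence: one coverage proportion per set member, in set order.

    Motifs are counted independently, so occurrences of *different* motifs may
    overlap one another and the vector components can sum to more than 1;
    these are coverage proportions, not a partition of the sequence.
    """
    if len(sequence) < WARN_LENGTH:
        logger.warning(
            "sequence %s is only %d bp; proportions on fragments shorter than "
            "%d bp (recommended >= %d bp) may be unreliable",
            sequence.id, len(sequence), WARN_LENGTH, RECOMMENDED_LENGTH,
        )
    text = sequence.residues
    values = np.array(
        [count_occurrences(m, text, mode) * len(m) / len(text) for m in spectrum_set],
        dtype=float,
    )
    return ProfileVector(sequence.id, spectrum_set.name, values)


@dataclass
class ProfileMatrix:
    """Sequences x motifs table of coverage proportions for one spectrum set.

    Row order follows the input sequence order; column order is the spectrum
    set's lexicographic motif order.
    """

    set_name: str
    sequence_ids: list[str]
    motifs: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("profile matrix values must be 2-dimensional")
        if self.values.shape != (len(self.sequence_ids), len(self.motifs)):
            raise ValueError(
                f"profile matrix shape {self.values.shape} does not match "
                f"{len(self.sequence_ids)} ids x {len(self.motifs)} motifs"
            )
        dupes = {s for s in self.sequence_ids if self.sequence_ids.count(s) > 1}
        if dupes:
            raise ValueError(f"duplicate sequence ids: {sorted(dupes)}")

    @property
    def n_sequences(self) -> int:
        return len(self.sequence_ids)

    def row(self, sequence_id: str) -> np.ndarray:
        return self.values[self.sequence_ids.index(sequence_id)]

    def subset(self, sequence_ids: Iterable[str]) -> "ProfileMatrix":
        """Row-subset preserving this matrix's row order."""
        keep = set(sequence_ids)
        idx = [i for i, s in enumerate(self.sequence_ids) if s in keep]
        missing = keep - {self.sequence_ids[i] for i in idx}
        if missing:
            raise KeyError(f"ids not in profile matrix: {sorted(missing)}")
        return ProfileMatrix(
            self.set_name,
            [self.sequence_ids[i] for i in idx],
            self.motifs,
            self.values[idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.sequence_ids, name="sequence_id"),
            columns=list(self.motifs),
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", float_format="%.6g")

    @classmethod
    def from_tsv(cls, path, set_name: str = "") -> "ProfileMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(set_name, [str(i) for i in df.index], tuple(df.columns), df.values)


def profile_matrix(
    sequences: Sequence[SequenceRecord],
    spectrum_set: SpectrumSet,
    mode: str = "nonoverlapping",
) -> ProfileMatrix:
    """Profile a batch of sequences into one rectangular matrix."""
    if not sequences:
        raise ValueError("cannot profile an empty sequence list")
    rows = [profile(s, spectrum_set, mode).values for s in sequences]
    return ProfileMatrix(
        set_name=spectrum_set.name,
        sequence_ids=[s.id for s in sequences],
        motifs=spectrum_set.motifs,
        values=np.vstack(rows),
    )
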