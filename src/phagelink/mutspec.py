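"""Mutation-spectrum estimation for error-prone tail-fiber libraries.

The mutagenized amplicon is the 516-bp C-terminal fragment of the tail
fiber gene (gene-17 interval [1146, 1662) in 0-based half-open genome
coordinates, encoding gp17 residues 382-554).  Positions are 0-based
internally; the conventional 1..516 display index is internal + 1.

Reads are assumed position-anchored to the reference (mapping with an
external aligner is a pre-processing step outside this package); the
spectrum is naive per-position mismatch counting over the anchored reads.
Amino-acid substitution calls translate clone sequences codon-wise under
the standard genetic code; indels are flagged, not translated.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

__all__ = [
    "AmpliconReference",
    "AmpliconReads",
    "MutationSpectrum",
    "NtSubstitution",
    "AaCall",
    "CloneMutationRecord",
    "RecurrenceTally",
    "per_position_frequency",
    "mean_mutations_per_fragment",
    "uniformity_test",
    "aa_substitution_calls",
    "recurrence_tally",
]

_BASES = b"ACGT"


def _as_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()


@dataclass(frozen=True)
class AmpliconReference:
    """The amplified reference fragment with its coordinate anchors.

    ``gene_offset`` maps internal position 0 onto the gene coordinate
    (default 1146, 0-based); ``aa_offset`` is the residue index encoded by
    the first codon (default 382).
    """

    sequence: str
    gene_offset: int = 1146
    aa_offset: int = 382
    name: str = "tail-fiber-fragment"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if set(self.sequence) - set("ACGT"):
            raise ValueError("reference must be unambiguous A/C/G/T")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def as_bytes(self) -> np.ndarray:
        return _as_bytes(self.sequence)

    def require_codons(self) -> None:
        if len(self.sequence) % 3:
            raise ValueError("reference length not divisible by 3; "
                             "amino-acid analysis unavailable")

    def residue_index(self, codon_ordinal: int) -> int:
        """Residue number of the 0-based codon ordinal (first codon -> aa_offset)."""
        return self.aa_offset + codon_ordinal

    def gene_position(self, internal: int) -> int:
        """Gene coordinate (0-based) of an internal 0-based position."""
        return self.gene_offset + internal

    @classmethod
    def from_fasta(cls, path, **kwargs) -> "AmpliconReference":
        from Bio import SeqIO
        rec = next(SeqIO.parse(path, "fasta"))
        return cls(str(rec.seq), name=rec.id, **kwargs)


class AmpliconReads:
    """Full-length position-anchored reads as a dense byte matrix."""

    def __init__(self, matrix: np.ndarray) -> None:
        matrix = np.asarray(matrix, dtype=np.uint8)
        if matrix.ndim != 2:
            raise ValueError("read matrix must be 2-D (reads x positions)")
        self.matrix = matrix

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def read_length(self) -> int:
        return self.matrix.shape[1]

    def sequences(self) -> Iterable[str]:
        for row in self.matrix:
            yield row.tobytes().decode("ascii")

    @classmethod
    def from_sequences(cls, seqs: Sequence[str]) -> "AmpliconReads":
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError("from_sequences requires equal-length reads")
        return cls(np.stack([_as_bytes(s) for s in seqs]))

    @classmethod
    def from_fastq(cls, path) -> "AmpliconReads":
        from Bio import SeqIO
        return cls.from_sequences([str(r.seq) for r in SeqIO.parse(path, "fastq")])

    def to_fastq(self, path, quality: int = 40, prefix: str = "read") -> None:
        from Bio import SeqIO
        from Bio.SeqRecord import SeqRecord
        records = (
            SeqRecord(Seq(s), id=f"{prefix}{i}", description="",
                      letter_annotations={"phred_quality": [quality] * len(s)})
            for i, s in enumerate(self.sequences())
        )
        SeqIO.write(records, path, "fastq")


@dataclass
class MutationSpectrum:
    """Per-position mismatch counts/depths plus per-fragment load stats."""

    mismatches: np.ndarray
    depth: np.ndarray
    reference: AmpliconReference
    per_fragment_loads: Optional[np.ndarray] = None

    @property
    def frequency(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(self.depth > 0, self.mismatches / self.depth, np.nan)
        return freq

    @property
    def zero_depth_positions(self) -> np.ndarray:
        """Internal 0-based positions never covered by a read (flagged NaN)."""
        return np.flatnonzero(self.depth == 0)

    @property
    def mean_load(self) -> float:
        """Mean substitutions per fragment = sum of per-position frequencies."""
        return float(np.nansum(self.frequency))

    def load_histogram(self) -> Optional[np.ndarray]:
        if self.per_fragment_loads is None:
            return None
        return np.bincount(self.per_fragment_loads)

    def to_frame(self) -> pd.DataFrame:
        """Spectrum as position (1-based display) / depth / mismatches / frequency."""
        n = len(self.reference)
        return pd.DataFrame({
            "position": np.arange(1, n + 1),
            "gene_position": self.reference.gene_offset + np.arange(n),
            "depth": self.depth,
            "mismatches": self.mismatches,
            "frequency": self.frequency,
        })


ReadsLike = Union[AmpliconReads, Sequence[str], Sequence[tuple[int, str]]]


def per_position_frequency(reads: ReadsLike, ref: AmpliconReference) -> MutationSpectrum:
    """Count mismatches against the reference at every position.

    ``reads`` may be an :class:`AmpliconReads` matrix (full length), plain
    strings (full length) or ``(anchor_offset, sequence)`` pairs for
    partial reads.  A read running past the reference end is rejected.
    """
    n = len(ref)
    ref_bytes = ref.as_bytes
    if isinstance(reads, AmpliconReads):
        if reads.read_length != n:
            raise ValueError(f"read length {reads.read_length} != reference length {n} "
                             "(anchor partial reads as (offset, seq) pairs)")
        mism_mat = reads.matrix != ref_bytes[None, :]
        mismatches = mism_mat.sum(axis=0).astype(np.int64)
        depth = np.full(n, len(reads), dtype=np.int64)
        loads = mism_mat.sum(axis=1).astype(np.int64)
        return MutationSpectrum(mismatches, depth, ref, per_fragment_loads=loads)

    mismatches = np.zeros(n, dtype=np.int64)
    depth = np.zeros(n, dtype=np.int64)
    loads = []
    full_length = True
    for item in reads:
        if isinstance(item, str):
            offset, seq = 0, item
        else:
            offset, seq = item
        if offset < 0 or offset + len(seq) > n:
            raise ValueError(f"read (offset={offset}, len={len(seq)}) extends past the "
                             f"{n}-bp reference; anchor or trim it first")
        sl = slice(offset, offset + len(seq))
        mism = _as_bytes(seq) != ref_bytes[sl]
        mismatches[sl] += mism
        depth[sl] += 1
        loads.append(int(mism.sum()))
        full_length &= len(seq) == n
    return MutationSpectrum(mismatches, depth, ref,
                            per_fragment_loads=np.array(loads, dtype=np.int64)
                            if full_length and loads else None)


def mean_mutations_per_fragment(obj, ref: AmpliconReference | None = None) -> float:
    """Mean substitution count per fragment.

    Accepts a :class:`MutationSpectrum` (mean = sum of per-position
    frequencies) or raw fragment sequences plus a reference.
    """
    if isinstance(obj, MutationSpectrum):
        return obj.mean_load
    if ref is None:
        raise ValueError("a reference is required when passing raw fragments")
    spectrum = per_position_frequency(obj, ref)
    if spectrum.per_fragment_loads is not None:
        return float(np.mean(spectrum.per_fragment_loads))
    return spectrum.mean_load


class UniformityResult(NamedTuple):
    statistic: float
    pvalue: float
    dof: int
    bins: int


def uniformity_test(spectrum: MutationSpectrum, bins: int = 20) -> UniformityResult:
    """Chi-square goodness of fit of positional mutation counts vs uniform.

    Positions are grouped into ``bins`` near-equal bins (expected counts
    proportional to bin width); refuses when any expected count drops
    below 5, the usual chi-square validity floor.
    """
    counts = np.asarray(spectrum.mismatches, dtype=float)
    groups = np.array_split(counts, bins)
    observed = np.array([g.sum() for g in groups])
    widths = np.array([len(g) for g in groups], dtype=float)
    total = observed.sum()
    expected = total * widths / widths.sum()
    if np.any(expected < 5):
        raise ValueError(f"expected count below 5 in at least one of {bins} bins "
                         f"(total mutations {total:.0f}); too few mutations to test")
    stat, p = stats.chisquare(observed, expected)
    return UniformityResult(float(stat), float(p), bins - 1, bins)


class NtSubstitution(NamedTuple):
    position: int  # internal, 0-based
    ref: str
    alt: str


class AaCall(NamedTuple):
    residue: int
    ref_aa: str
    alt_aa: str
    silent: bool

    def __str__(self) -> str:
        return f"{self.ref_aa}{self.residue}{self.alt_aa}"


@dataclass
class CloneMutationRecord:
    """Substitution calls for one sequenced clone against one reference."""

    clone_id: str
    host: str
    reference: AmpliconReference
    nt_substitutions: list[NtSubstitution]
    aa_calls: list[AaCall]
    has_indel: bool = False

    def non_silent(self) -> list[AaCall]:
        return [c for c in self.aa_calls if not c.silent]


def aa_substitution_calls(clone_seq: str, ref: AmpliconReference,
                          clone_id: str = "clone", host: str = "") -> CloneMutationRecord:
    """Call nucleotide and amino-acid substitutions for a clone sequence.

    The clone must align to the reference without indels; a length
    mismatch flags an indel and returns a partial (untranslated) record.
    Codons are translated under the standard genetic code; a call is
    silent iff the residue is unchanged.  Multi-nucleotide changes within
    one codon yield a single amino-acid call.
    """
    ref.require_codons()
    clone_seq = clone_seq.upper()
    if len(clone_seq) != len(ref):
        return CloneMutationRecord(clone_id, host, ref, [], [], has_indel=True)
    ref_seq = ref.sequence
    nt_subs = [NtSubstitution(i, ref_seq[i], clone_seq[i])
               for i in range(len(ref_seq)) if clone_seq[i] != ref_seq[i]]
    aa_calls = []
    for ordinal in sorted({s.position // 3 for s in nt_subs}):
        start = 3 * ordinal
        ref_aa = str(Seq(ref_seq[start:start + 3]).translate())
        alt_aa = str(Seq(clone_seq[start:start + 3]).translate())
        aa_calls.append(AaCall(ref.residue_index(ordinal), ref_aa, alt_aa,
                               silent=ref_aa == alt_aa))
    return CloneMutationRecord(clone_id, host, ref, nt_subs, aa_calls)


@dataclass
class RecurrenceTally:
    """How often each amino-acid substitution recurs across clones."""

    non_silent: Counter
    silent: Counter

    def most_common(self, n: int | None = None):
        return self.non_silent.most_common(n)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"substitution": s, "count": c, "silent": False}
                for s, c in self.non_silent.most_common()]
        rows += [{"substitution": s, "count": c, "silent": True}
                 for s, c in self.silent.most_common()]
        return pd.DataFrame(rows, columns=["substitution", "count", "silent"])


def recurrence_tally(records: Sequence[CloneMutationRecord]) -> RecurrenceTally:
    """Tally distinct amino-acid substitutions over clone records.

    All records must share one reference; silent calls are tallied
    separately from non-silent ones.
    """
    refs = {r.reference.sequence for r in records}
    if len(refs) > 1:
        raise ValueError("records mix different references")
    non_silent: Counter = Counter()
    silent: Counter = Counter()
    for rec in records:
        for call in rec.aa_calls:
            (silent if call.silent else non_silent)[str(call)] += 1
    return RecurrenceTally(non_silent, silent)
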