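"""Fragment/overlap design for phage genome edits and in-silico assembly.

An edit plan (insertions, deletions, point substitutions on a linear
reference) is compiled into an ordered set of PCR fragments of at most
12 kbp.  Adjacent fragments share either a natural genomic overlap
(default 50 bp, printed junction coordinates treated as midpoints with
symmetric extension) or a designed 20-bp orthogonal tag appended to both
junction ends — the strategy used to bridge deletions and suppress
mis-annealing ("leak").

Assembly is verified in silico by simulating exonuclease chew-back: the
3' ends of each double-stranded fragment are resected, exposing 5'
single-stranded overhangs; two ends join when the exposed sequences are
exact reverse complements over at least ``min_anneal`` bases.  A complete
product exists iff the junction graph contains a single simple path
through all fragments; dropping any fragment must break the path (the
negative control expected to yield no phage).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from Bio.Seq import Seq

__all__ = [
    "MAX_FRAGMENT_LEN",
    "Insertion",
    "Deletion",
    "Substitution",
    "EditPlan",
    "EditedGenome",
    "OverlapSpec",
    "Fragment",
    "FragmentPlan",
    "AssemblyResult",
    "apply_edit_plan",
    "plan_fragments",
    "crosstalk_matrix",
    "simulate_assembly",
    "wallace_tm",
]

#: long-PCR practical ceiling used throughout the fragment planner
MAX_FRAGMENT_LEN = 12_000


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# -- edits -----------------------------------------------------------------

@dataclass(frozen=True)
class Insertion:
    locus: int          # cassette inserted before this reference position
    cassette: str
    label: str = ""

    @property
    def interval(self) -> tuple[int, int]:
        return (self.locus, self.locus)


@dataclass(frozen=True)
class Deletion:
    start: int          # half-open [start, end) on the reference
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty/inverted deletion [{self.start}, {self.end})")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class Substitution:
    position: int
    ref: str
    alt: str
    label: str = ""

    @property
    def interval(self) -> tuple[int, int]:
        return (self.position, self.position + 1)


Edit = Union[Insertion, Deletion, Substitution]


@dataclass
class EditPlan:
    """A linear reference plus an ordered, non-overlapping set of edits."""

    reference: str
    edits: list[Edit] = field(default_factory=list)
    circular: bool = False

    def __post_init__(self) -> None:
        self.reference = self.reference.upper()


@dataclass
class EditedGenome:
    sequence: str
    #: (ref_start, ref_end, edited_start) per unedited segment, in order
    segments: list[tuple[int, int, int]]

    def ref_to_edited(self, pos: int) -> Optional[int]:
        """Map a reference coordinate onto the edited genome (None if deleted)."""
        for ref_start, ref_end, ed_start in self.segments:
            if ref_start <= pos < ref_end:
                return ed_start + (pos - ref_start)
        return None


def apply_edit_plan(plan: EditPlan) -> EditedGenome:
    """Apply edits left to right, building the edited sequence and the
    monotone coordinate map of the surviving reference segments."""
    n = len(plan.reference)
    edits = sorted(plan.edits, key=lambda e: e.interval)
    prev_end = 0
    last = None
    for e in edits:
        start, end = e.interval
        if start < 0 or end > n:
            raise ValueError(f"edit {e} outside genome bounds [0, {n})")
        if last is not None and start < prev_end:
            raise ValueError(f"overlapping edits: {last} and {e}")
        prev_end, last = max(prev_end, end if end > start else start + 1), e

    parts: list[str] = []
    segments: list[tuple[int, int, int]] = []
    cursor = 0      # reference coordinate
    out_len = 0

    def emit_ref(upto: int) -> None:
        nonlocal cursor, out_len
        if upto > cursor:
            parts.append(plan.reference[cursor:upto])
            segments.append((cursor, upto, out_len))
            out_len += upto - cursor
            cursor = upto

    for e in edits:
        if isinstance(e, Insertion):
            emit_ref(e.locus)
            parts.append(e.cassette.upper())
            out_len += len(e.cassette)
        elif isinstance(e, Deletion):
            emit_ref(e.start)
            cursor = e.end
        elif isinstance(e, Substitution):
            emit_ref(e.position)
            if plan.reference[e.position] != e.ref.upper():
                raise ValueError(f"substitution {e}: reference has "
                                 f"{plan.reference[e.position]!r} at {e.position}")
            parts.append(e.alt.upper())
            segments.append((e.position, e.position + 1, out_len))
            out_len += 1
            cursor = e.position + 1
        else:
            raise TypeError(f"unknown edit type {type(e).__name__}")
    emit_ref(n)
    return EditedGenome("".join(parts), segments)


# -- fragment planning -----------------------------------------------------

@dataclass(frozen=True)
class OverlapSpec:
    """Junction strategy: natural genomic overlap or orthogonal tags."""

    mode: str = "natural"           # "natural" | "orthogonal"
    length: int = 50
    tags: tuple[str, ...] = ()      # user-supplied orthogonal set (orthogonal mode)

    def __post_init__(self) -> None:
        if self.mode not in ("natural", "orthogonal"):
            raise ValueError(f"unknown overlap mode {self.mode!r}")
        if self.length < 1:
            raise ValueError("overlap length must be >= 1")
        if self.mode == "orthogonal":
            bad = [t for t in self.tags if len(t) != self.length]
            if bad:
                raise ValueError(f"orthogonal tags must all be {self.length} bp")

    @classmethod
    def natural(cls, length: int = 50) -> "OverlapSpec":
        return cls("natural", length)

    @classmethod
    def orthogonal(cls, tags: Sequence[str], length: int = 20) -> "OverlapSpec":
        return cls("orthogonal", length, tuple(t.upper() for t in tags))


@dataclass(frozen=True)
class PrimerPair:
    sense: str
    antisense: str
    sense_overhang: str = ""
    antisense_overhang: str = ""


@dataclass
class Fragment:
    name: str
    start: int          # on the expected product, half-open
    end: int
    sequence: str
    left_overlap: str = ""
    right_overlap: str = ""
    primers: Optional[PrimerPair] = None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class FragmentPlan:
    fragments: list[Fragment]
    overlap: OverlapSpec
    expected_product: str

    def sequences(self) -> list[str]:
        return [f.sequence for f in self.fragments]


def wallace_tm(seq: str) -> float:
    """Wallace-rule melting temperature 2(A+T) + 4(G+C), in Celsius."""
    s = seq.upper()
    return 2.0 * (s.count("A") + s.count("T")) + 4.0 * (s.count("G") + s.count("C"))


def _annealing_region(seq: str, target_tm: float = 60.0,
                      min_len: int = 20, max_len: int = 30) -> str:
    for ln in range(min_len, max_len + 1):
        if wallace_tm(seq[:ln]) >= target_tm:
            return seq[:ln]
    return seq[:max_len]


def _design_primers(fragment_seq: str, left_overhang: str = "",
                    right_overhang: str = "") -> PrimerPair:
    sense = _annealing_region(fragment_seq)
    antisense = _annealing_region(_revcomp(fragment_seq))
    return PrimerPair(sense=left_overhang + sense,
                      antisense=right_overhang + antisense,
                      sense_overhang=left_overhang,
                      antisense_overhang=right_overhang)


def plan_fragments(genome: str, breakpoints: Sequence[int] | None = None,
                   max_len: int | None = None,
                   overlap: OverlapSpec = OverlapSpec()) -> FragmentPlan:
    """Cut a genome into <= 12 kbp PCR fragments joined by overlaps.

    ``breakpoints`` are junction midpoints; in natural mode each junction
    is extended symmetrically by half the overlap length on either side so
    adjacent fragments share exactly ``overlap.length`` bases.  In
    orthogonal mode fragments are cut exactly at breakpoints and the k-th
    junction's tag is appended to both mating ends (the tag remains in the
    assembled product).  ``max_len`` instead auto-splits evenly.
    """
    genome = genome.upper()
    n = len(genome)
    ov = overlap.length
    if breakpoints is None:
        if max_len is None:
            breakpoints = []
        else:
            span = max_len - ov  # leave room for the overlap extensions
            k = max(1, -(-n // span))
            breakpoints = [round(i * n / k) for i in range(1, k)]
    breakpoints = sorted(int(b) for b in breakpoints)
    if breakpoints and (breakpoints[0] < ov or breakpoints[-1] > n - ov):
        raise ValueError("breakpoints must leave at least one overlap length "
                         "to each genome end")
    if any(b2 - b1 <= ov for b1, b2 in zip(breakpoints, breakpoints[1:])):
        raise ValueError("breakpoints closer than the overlap length")

    bounds = [0, *breakpoints, n]
    fragments: list[Fragment] = []

    if overlap.mode == "natural":
        left_ext, right_ext = ov // 2, ov - ov // 2
        expected = genome
        for i, (b1, b2) in enumerate(zip(bounds, bounds[1:])):
            start = b1 - left_ext if i > 0 else 0
            end = b2 + right_ext if i < len(bounds) - 2 else n
            seq = genome[start:end]
            left = genome[start:start + ov] if i > 0 else ""
            right = genome[end - ov:end] if i < len(bounds) - 2 else ""
            frag = Fragment(f"F{i + 1}", start, end, seq, left, right,
                            primers=_design_primers(seq))
            fragments.append(frag)
    else:
        n_junctions = len(bounds) - 2
        if len(overlap.tags) < n_junctions:
            raise ValueError(f"{n_junctions} junctions but only "
                             f"{len(overlap.tags)} orthogonal tags supplied")
        tags = list(overlap.tags[:n_junctions])
        pieces = []
        for i, (b1, b2) in enumerate(zip(bounds, bounds[1:])):
            left_tag = tags[i - 1] if i > 0 else ""
            right_tag = tags[i] if i < n_junctions else ""
            core = genome[b1:b2]
            seq = left_tag + core + right_tag
            frag = Fragment(f"F{i + 1}", b1, b2, seq, left_tag, right_tag,
                            primers=_design_primers(core, left_tag,
                                                    _revcomp(right_tag) if right_tag else ""))
            fragments.append(frag)
            pieces.append(core if i == 0 else tags[i - 1] + core)
        expected = "".join(pieces)
        # recompute fragment coordinates on the tagged product
        pos = 0
        for i, frag in enumerate(fragments):
            start = pos - (len(frag.left_overlap) if i > 0 else 0)
            frag.start, frag.end = start, start + len(frag.sequence)
            pos = frag.end - (len(frag.right_overlap) if i < len(fragments) - 1 else 0)

    for frag in fragments:
        if len(frag) > MAX_FRAGMENT_LEN:
            raise ValueError(f"fragment {frag.name} is {len(frag)} bp "
                             f"(> {MAX_FRAGMENT_LEN}); add breakpoints or use max_len")
    return FragmentPlan(fragments, overlap, expected)


# -- crosstalk scoring -----------------------------------------------------

def _longest_complementary_match(a: str, b: str) -> int:
    """Length of the longest exact complementary stretch between two
    single-stranded ends (longest common substring of a and revcomp(b))."""
    x, y = a.upper(), _revcomp(b.upper())
    best = 0
    prev = [0] * (len(y) + 1)
    for i in range(1, len(x) + 1):
        cur = [0] * (len(y) + 1)
        for j in range(1, len(y) + 1):
            if x[i - 1] == y[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def crosstalk_matrix(ends: Sequence[str],
                     partners: Sequence[tuple[int, int]] = (),
                     threshold: int = 10):
    """Pairwise complementarity scores between single-stranded ends.

    ``score[i, j]`` is the longest exact complementary match between ends
    i and j.  Pairs scoring >= ``threshold`` are flagged, excluding
    declared partner pairs (which are complementary by construction).
    Returns ``(matrix, flagged_pairs)``.
    """
    if len(ends) < 2:
        raise ValueError("need at least two end sequences")
    k = len(ends)
    partner_set = {frozenset(p) for p in partners}
    score = np.zeros((k, k), dtype=int)
    flagged = []
    for i in range(k):
        for j in range(i, k):
            s = _longest_complementary_match(ends[i], ends[j])
            score[i, j] = score[j, i] = s
            if s >= threshold and frozenset((i, j)) not in partner_set and i != j:
                flagged.append((i, j, s))
    return score, flagged


# -- chew-back / annealing simulation -------------------------------------

@dataclass
class AssemblyResult:
    products: list[str]
    complete: bool
    diagnostics: dict
    edges: list[tuple[tuple[int, int], tuple[int, int], int]]

    @property
    def product(self) -> Optional[str]:
        return self.products[0] if self.complete else None

    def matches(self, reference: str) -> bool:
        """Does the complete product equal the reference in either strand?"""
        if not self.complete:
            return False
        p = self.products[0].upper()
        ref = reference.upper()
        return p == ref or p == _revcomp(ref)


def _junction_overlap(left: str, right: str, chewback: int, min_anneal: int) -> int:
    """Longest k in [min_anneal, chewback] with left suffix == right prefix."""
    lim = min(chewback, len(left), len(right))
    for k in range(lim, min_anneal - 1, -1):
        if left[-k:] == right[:k]:
            return k
    return 0


def simulate_assembly(fragments, chewback_length: int = 60,
                      min_anneal: int = 15) -> AssemblyResult:
    """Simulate chew-back/annealing assembly of double-stranded fragments.

    Chew-back is modelled as a deterministic resection of ``chewback_length``
    bases from each 3' end, exposing 5' single-stranded overhangs; two
    fragment ends join when the exposed sequences are exact reverse
    complements over >= ``min_anneal`` bases — equivalently, when one
    fragment's top-strand suffix equals the other's prefix within the
    chewed window.  Fragments may be supplied in either orientation and
    any order.  Products follow maximal unambiguous junction chains; the
    result is complete iff a single chain uses every fragment once.
    """
    seqs = [f.sequence if isinstance(f, Fragment) else str(f) for f in fragments]
    seqs = [s.upper() for s in seqs]
    nfrag = len(seqs)
    if nfrag == 0:
        return AssemblyResult([], False, {"n_fragments": 0, "reason": "no fragments"}, [])
    if nfrag == 1:
        return AssemblyResult([seqs[0]], True,
                              {"n_fragments": 1, "n_products": 1,
                               "fragments_in_products": [0],
                               "unjoined_fragments": [], "ambiguous_ends": [],
                               "missing_junctions": 0}, [])

    # nodes: (fragment index, orientation); orientation 1 = reverse complement
    oriented = {(i, o): (seqs[i] if o == 0 else _revcomp(seqs[i]))
                for i in range(nfrag) for o in (0, 1)}
    edges = []
    succ: dict[tuple[int, int], list] = {}
    pred: dict[tuple[int, int], list] = {}
    for a, sa in oriented.items():
        for b, sb in oriented.items():
            if a[0] == b[0]:
                continue
            k = _junction_overlap(sa, sb, chewback_length, min_anneal)
            if k:
                edges.append((a, b, k))
                succ.setdefault(a, []).append((b, k))
                pred.setdefault(b, []).append((a, k))

    ambiguous = sorted(a for a, lst in succ.items() if len(lst) > 1)
    # walk unambiguous chains from nodes with no incoming junction
    paths = []
    seen_paths = set()
    for start in oriented:
        if start in pred:
            continue
        path = [start]
        used = {start[0]}
        node = start
        while node in succ and len(succ[node]) == 1:
            (nxt, k), = succ[node]
            if len(pred.get(nxt, [])) != 1 or nxt[0] in used:
                break
            path.append(nxt)
            used.add(nxt[0])
            node = nxt
        if len(path) < 2:
            continue
        mirror = tuple((i, 1 - o) for i, o in reversed(path))
        if mirror in seen_paths:
            continue
        seen_paths.add(tuple(path))
        paths.append(path)

    def _assemble(path) -> str:
        out = oriented[path[0]]
        for a, b in zip(path, path[1:]):
            k = next(kk for (bb, kk) in succ[a] if bb == b)
            out += oriented[b][k:]
        return out

    # prefer the orientation family with more fragments as supplied
    def _canonical(path):
        fwd = sum(1 for _, o in path if o == 0)
        mirror = [(i, 1 - o) for i, o in reversed(path)]
        m_fwd = len(path) - fwd
        if m_fwd > fwd or (m_fwd == fwd and mirror[0][0] < path[0][0]):
            return mirror
        return path

    paths = [_canonical(p) for p in paths]
    products = sorted((_assemble(p) for p in paths), key=len, reverse=True)
    covered = {i for p in paths for i, _ in p}
    complete = (len(paths) == 1 and len(paths[0]) == nfrag)
    missing = []
    if not complete:
        missing = sorted(set(range(nfrag)) - covered)
    diagnostics = {
        "n_fragments": nfrag,
        "n_products": len(products),
        "fragments_in_products": sorted(covered),
        "unjoined_fragments": missing,
        "ambiguous_ends": ambiguous,
        "missing_junctions": max(0, nfrag - 1 - len({frozenset((a[0], b[0]))
                                                     for a, b, _ in edges})),
    }
    return AssemblyResult(products, complete, diagnostics, edges)
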