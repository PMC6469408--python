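"""Calling fixed interspecies differences in TSS-relative coordinates.

Consumes a pairwise alignment of an upstream/promoter fragment from two
sister species (species a = the reference species whose genome annotation
anchors the transcription start site), calls substitution and indel events,
removes apparent differences that are in fact polymorphisms segregating
within the reference species, classifies each event into a regulatory
domain, and computes per-fragment substitution proportions.

Coordinates are TSS-relative with no position 0: position -1 is the base
immediately upstream of the TSS and +1 the first transcribed base, so an
interval -1123..+518 spans exactly 1123 + 518 = 1641 positions.  Internally
events live on the 1-based ungapped index of the species-a sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "Feature",
    "SequencedFragment",
    "SubstitutionEvent",
    "PolymorphismEvidence",
    "tss_to_index",
    "index_to_tss",
    "call_differences",
    "filter_shared_polymorphisms",
    "classify_domain",
    "annotate_domains",
    "substitution_proportion",
]

_BASES = frozenset("ACGT")

# regulatory domain windows, TSS-relative
PROMOTER = (-200, 200)
PROMOTER_PROXIMAL = (-500, -201)
PROMOTER_DISTAL_MAX = -501  # PD is strictly < -500


@dataclass(frozen=True)
class Feature:
    """Annotated interval on a fragment, in TSS-relative coordinates.

    ``feature_type`` is one of ``CDS``, ``transcript``, ``UTR5`` or
    ``neighbor_gene:<name>``.
    """

    feature_type: str
    start: int
    end: int  # inclusive

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


def _span_length(tss_start: int, tss_end: int) -> int:
    if tss_start >= tss_end:
        raise ValueError("tss_start must be < tss_end")
    n = tss_end - tss_start + 1
    if tss_start < 0 < tss_end:
        n -= 1  # no position 0
    return n


def tss_to_index(tss_position: int, tss_start: int, tss_end: int) -> int:
    """Map a TSS-relative position to its 1-based ordinal index in the fragment."""
    if tss_position == 0:
        raise ValueError("TSS-relative coordinates have no position 0")
    if not tss_start <= tss_position <= tss_end:
        raise ValueError(
            f"position {tss_position} outside fragment {tss_start}..{tss_end}"
        )
    idx = tss_position - tss_start + 1
    if tss_start < 0 < tss_position:
        idx -= 1
    return idx


def index_to_tss(index: int, tss_start: int, tss_end: int) -> int:
    """Inverse of :func:`tss_to_index`."""
    n = _span_length(tss_start, tss_end)
    if not 1 <= index <= n:
        raise ValueError(f"index {index} outside 1..{n}")
    pos = tss_start + index - 1
    if tss_start < 0 and pos >= 0:
        pos += 1
    return pos


@dataclass
class SequencedFragment:
    """An aligned interspecies sequence pair anchored at a TSS."""

    gene: str
    tss_start: int
    tss_end: int
    seq_a: str  # reference species, aligned (may contain '-')
    seq_b: str
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.seq_a = self.seq_a.upper()
        self.seq_b = self.seq_b.upper()
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError(
                f"{self.gene}: aligned sequences differ in length "
                f"({len(self.seq_a)} vs {len(self.seq_b)})"
            )
        ungapped = len(self.seq_a) - self.seq_a.count("-")
        if ungapped != self.n_positions:
            raise ValueError(
                f"{self.gene}: ungapped species-a length {ungapped} does not match "
                f"the {self.n_positions} positions of {self.tss_start}..{self.tss_end}"
            )

    @property
    def n_positions(self) -> int:
        return _span_length(self.tss_start, self.tss_end)

    def tss_to_index(self, pos: int) -> int:
        return tss_to_index(pos, self.tss_start, self.tss_end)

    def index_to_tss(self, idx: int) -> int:
        return index_to_tss(idx, self.tss_start, self.tss_end)

    @property
    def ungapped_a(self) -> str:
        return self.seq_a.replace("-", "")


@dataclass
class SubstitutionEvent:
    """One interspecies difference (SNV or collapsed indel)."""

    gene: str
    tss_position: int  # leftmost affected base for indels
    kind: str  # SNV | deletion | insertion
    allele_a: str
    allele_b: str
    domain: str | None = None
    fixed: bool | None = None  # None = polymorphism screen not yet applied


def call_differences(fragment: SequencedFragment) -> list[SubstitutionEvent]:
    """Call one event per mismatch column / per maximal gap run.

    Consecutive gap columns in one species collapse to a single indel event
    reported at the leftmost affected species-a base (insertions take the
    position of the preceding species-a base).  Columns containing ambiguity
    codes are skipped with a warning.  ``fixed`` is left undetermined.
    """
    events: list[SubstitutionEvent] = []
    a, b = fragment.seq_a, fragment.seq_b
    a_pos = 0  # ungapped species-a index processed so far
    col = 0
    n_cols = len(a)
    n_skipped = 0
    while col < n_cols:
        ca, cb = a[col], b[col]
        if ca != "-" and cb != "-":
            a_pos += 1
            if ca != cb:
                if ca in _BASES and cb in _BASES:
                    events.append(
                        SubstitutionEvent(
                            gene=fragment.gene,
                            tss_position=fragment.index_to_tss(a_pos),
                            kind="SNV",
                            allele_a=ca,
                            allele_b=cb,
                        )
                    )
                else:
                    n_skipped += 1
            col += 1
        elif cb == "-" and ca != "-":
            # deletion in species b: collapse the maximal run
            start_a_pos = a_pos + 1
            run_a = []
            while col < n_cols and b[col] == "-" and a[col] != "-":
                run_a.append(a[col])
                a_pos += 1
                col += 1
            events.append(
                SubstitutionEvent(
                    gene=fragment.gene,
                    tss_position=fragment.index_to_tss(start_a_pos),
                    kind="deletion",
                    allele_a="".join(run_a),
                    allele_b="-" * len(run_a),
                )
            )
        elif ca == "-" and cb != "-":
            # insertion in species b, anchored at the preceding species-a base
            run_b = []
            while col < n_cols and a[col] == "-" and b[col] != "-":
                run_b.append(b[col])
                col += 1
            anchor = a_pos if a_pos >= 1 else 1
            events.append(
                SubstitutionEvent(
                    gene=fragment.gene,
                    tss_position=fragment.index_to_tss(anchor),
                    kind="insertion",
                    allele_a="-" * len(run_b),
                    allele_b="".join(run_b),
                )
            )
        else:  # gap in both — alignment padding, no event
            col += 1
    if n_skipped:
        logger.warning(
            "%s: skipped %d columns with ambiguity codes", fragment.gene, n_skipped
        )
    return events


@dataclass
class PolymorphismEvidence:
    """Alleles observed among conspecific (species-a) strains, per site.

    Either supplied directly as a position -> allele-set map, or derived from
    raw strain reads: a read contributes evidence only if its global identity
    to the best-matching window of the species-a fragment exceeds
    ``min_identity`` (the >90% identity matching contract).
    """

    alleles: dict[int, set[str]] = field(default_factory=dict)

    @classmethod
    def from_reads(
        cls,
        reads: Iterable[str],
        fragment: SequencedFragment,
        min_identity: float = 0.9,
    ) -> "PolymorphismEvidence":
        ref = fragment.ungapped_a
        evidence: dict[int, set[str]] = {}
        for read in reads:
            read = read.upper()
            L = len(read)
            if L == 0 or L > len(ref):
                continue
            best_ident, best_off = -1.0, 0
            for off in range(len(ref) - L + 1):
                matches = sum(1 for r, s in zip(read, ref[off : off + L]) if r == s)
                ident = matches / L
                if ident > best_ident:
                    best_ident, best_off = ident, off
            if best_ident <= min_identity:
                continue
            for k, base in enumerate(read):
                if base in _BASES:
                    pos = fragment.index_to_tss(best_off + k + 1)
                    evidence.setdefault(pos, set()).add(base)
        return cls(alleles=evidence)

    def alleles_at(self, tss_position: int) -> set[str]:
        return self.alleles.get(tss_position, set())


def filter_shared_polymorphisms(
    events: Sequence[SubstitutionEvent], evidence: PolymorphismEvidence | None
) -> list[SubstitutionEvent]:
    """Resolve the ``fixed`` flag of every event.

    An event is a shared polymorphism (``fixed = False``) iff the species-b
    allele is present in the species-a strain evidence at its site.  Sites
    without evidence count as "no polymorphism observed".  Returns only the
    fixed events; the input events are mutated in place with the resolved flag.
    """
    fixed_events = []
    for ev in events:
        shared = False
        if evidence is not None:
            obs = evidence.alleles_at(ev.tss_position)
            if ev.kind == "SNV":
                shared = ev.allele_b in obs
            else:
                shared = ev.allele_b in obs or "-" in obs and ev.kind == "deletion"
        ev.fixed = not shared
        if ev.fixed:
            fixed_events.append(ev)
    return fixed_events


def classify_domain(tss_position: int, features: Sequence[Feature] = ()) -> str:
    """Assign the regulatory-domain label of a position.

    Annotated features win over the distance windows: CDS first, then
    transcript/5'UTR, then neighbouring-gene annotations; a feature hit that
    also falls in the promoter window (-200..+200) is reported with the
    overlap noted, e.g. ``CDS/P``.  Outside features the windows apply:
    P = promoter (-200..+200), PP = promoter proximal (-500..-201),
    PD = promoter distal (< -500); anything else is ``other``.
    """
    if tss_position == 0:
        raise ValueError("no position 0 in TSS-relative coordinates")
    in_promoter = PROMOTER[0] <= tss_position <= PROMOTER[1]

    def feature_label(ft: str) -> str:
        if ft == "CDS":
            return "CDS"
        if ft == "UTR5":
            return "T(5'UTR)"
        if ft == "transcript":
            return "T"
        if ft.startswith("neighbor_gene:"):
            return ft.split(":", 1)[1]
        return ft

    for ftype in ("CDS", "UTR5", "transcript"):
        for f in features:
            if f.feature_type == ftype and f.contains(tss_position):
                label = feature_label(ftype)
                return f"{label}/P" if in_promoter else label
    for f in features:
        if f.feature_type.startswith("neighbor_gene:") and f.contains(tss_position):
            label = feature_label(f.feature_type)
            return f"{label}/P" if in_promoter else label
    if in_promoter:
        return "P"
    if PROMOTER_PROXIMAL[0] <= tss_position <= PROMOTER_PROXIMAL[1]:
        return "PP"
    if tss_position <= PROMOTER_DISTAL_MAX:
        return "PD"
    return "other"


def annotate_domains(
    events: Sequence[SubstitutionEvent], features: Sequence[Feature] = ()
) -> list[SubstitutionEvent]:
    """Fill the ``domain`` field of every event (in place; returns the list)."""
    for ev in events:
        ev.domain = classify_domain(ev.tss_position, features)
    return list(events)


def substitution_proportion(
    events: Sequence[SubstitutionEvent] | int, length: int
) -> tuple[float, float]:
    """Fixed-substitution proportion of a fragment.

    Each event — indels included — counts once; the proportion is the event
    count over the fragment length.  Returns ``(unrounded, rounded_3dp)``.
    """
    if length < 1:
        raise ValueError("fragment length must be >= 1")
    count = events if isinstance(events, int) else len(events)
    if not isinstance(events, int) and any(ev.fixed is False for ev in events):
        raise ValueError("substitution_proportion expects fixed events only")
    raw = count / length
    return raw, round(raw, 3)
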