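"""Amplicon alignment, repair-event extraction and indel-pattern classification.

The entry point for most users is :func:`classify_reads`, which takes merged
amplicon reads plus a :class:`TargetLocus` and produces an
:class:`OutcomeSpectrum`.  The individual steps — global alignment, event
extraction, left-normalization, microhomology detection, cut-site windowing
and pattern assignment — are exposed as separate functions so each can be
tested and reused on its own.

Coordinates are 0-based throughout.  Deletions and substitutions occupy
reference positions ``[start, start+length)``; insertions anchor at the
inter-base coordinate ``start`` (between reference positions ``start-1`` and
``start``).  The cut site is likewise an inter-base coordinate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align

from .patterns import (
    DEFAULT_MH_MIN,
    DEFAULT_WINDOW_BP,
    EDITED_PATTERNS,
    SMALL_DEL_MAX,
    UNEDITED,
)

__all__ = [
    "TargetLocus",
    "RepairEvent",
    "AlleleCall",
    "OutcomeSpectrum",
    "AlignmentScoring",
    "locate_cut_site",
    "align_read",
    "apply_events",
    "left_normalize",
    "detect_microhomology",
    "call_repair_events",
    "classify_allele",
    "classify_reads",
    "summarize_spectrum",
    "breakpoint_profile",
    "format_event",
    "parse_event",
]

PAM_LEN = 3  # NGG
CUT_OFFSET_FROM_PAM = 3  # SpCas9 blunt cut 3 nt 5' of the PAM


class ConfigurationError(ValueError):
    """Locus annotation is internally inconsistent."""


def locate_cut_site(
    protospacer_start: int,
    protospacer_len: int,
    pam_start: int,
    pam_strand: str = "+",
) -> int:
    """Return the blunt-cut inter-base coordinate for an SpCas9 site.

    On the ``+`` strand the NGG PAM immediately follows the protospacer and
    the cut falls 3 nt upstream (5') of it.  On the ``-`` strand the PAM
    (reverse-complement, CCN on the given strand) immediately precedes the
    protospacer and the geometry mirrors.

    Raises
    ------
    ConfigurationError
        If the PAM is not adjacent to the protospacer on the stated side.
    """
    if pam_strand == "+":
        if pam_start != protospacer_start + protospacer_len:
            raise ConfigurationError(
                f"PAM at {pam_start} is not adjacent to protospacer end "
                f"{protospacer_start + protospacer_len} on + strand"
            )
        return pam_start - CUT_OFFSET_FROM_PAM
    if pam_strand == "-":
        if pam_start + PAM_LEN != protospacer_start:
            raise ConfigurationError(
                f"PAM ending at {pam_start + PAM_LEN} is not adjacent to "
                f"protospacer start {protospacer_start} on - strand"
            )
        return pam_start + PAM_LEN + CUT_OFFSET_FROM_PAM
    raise ConfigurationError(f"pam_strand must be '+' or '-', got {pam_strand!r}")


@dataclass(frozen=True)
class TargetLocus:
    """A reference amplicon annotated with protospacer, PAM and cut site."""

    ref_seq: str
    protospacer_start: int
    protospacer_len: int = 20
    pam_start: int = -1
    pam_strand: str = "+"

    def __post_init__(self) -> None:
        if self.pam_start < 0:
            # Default: PAM immediately 3' of the protospacer on +.
            object.__setattr__(
                self, "pam_start", self.protospacer_start + self.protospacer_len
            )
        n = len(self.ref_seq)
        if not (0 <= self.protospacer_start
                and self.protospacer_start + self.protospacer_len <= n):
            raise ConfigurationError("protospacer outside reference")
        if not (0 <= self.pam_start and self.pam_start + PAM_LEN <= n):
            raise ConfigurationError("PAM outside reference")
        cut = locate_cut_site(
            self.protospacer_start, self.protospacer_len,
            self.pam_start, self.pam_strand,
        )
        if not (0 < cut < n):
            raise ConfigurationError("cut site not strictly inside reference")

    @property
    def cut_site(self) -> int:
        return locate_cut_site(
            self.protospacer_start, self.protospacer_len,
            self.pam_start, self.pam_strand,
        )

    @property
    def pam_is_downstream(self) -> bool:
        """True when the PAM lies 3' (right) of the cut on the reference."""
        return self.pam_strand == "+"


@dataclass(frozen=True)
class RepairEvent:
    """A single normalized sequence alteration in reference coordinates."""

    kind: str  # {"insertion", "deletion", "substitution"}
    start: int
    length: int
    inserted_seq: str = ""
    sub_bases: tuple[tuple[int, str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion", "substitution"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("event length must be >= 1")
        if self.kind == "insertion" and len(self.inserted_seq) != self.length:
            raise ValueError("insertion length does not match inserted_seq")
        if self.kind == "substitution" and len(self.sub_bases) != self.length:
            raise ValueError("substitution length does not match sub_bases")

    @property
    def end(self) -> int:
        """One-past-last reference position (== start for insertions)."""
        return self.start if self.kind == "insertion" else self.start + self.length


def format_event(ev: RepairEvent) -> str:
    """Compact string form: ``D:5:8``, ``I:17:1:T``, ``S:16:C>A``."""
    if ev.kind == "deletion":
        return f"D:{ev.start}:{ev.length}"
    if ev.kind == "insertion":
        return f"I:{ev.start}:{ev.length}:{ev.inserted_seq}"
    ref = "".join(b[1] for b in ev.sub_bases)
    alt = "".join(b[2] for b in ev.sub_bases)
    return f"S:{ev.start}:{ref}>{alt}"


def parse_event(text: str) -> RepairEvent:
    """Inverse of :func:`format_event`."""
    parts = text.split(":")
    if parts[0] == "D":
        return RepairEvent("deletion", int(parts[1]), int(parts[2]))
    if parts[0] == "I":
        return RepairEvent("insertion", int(parts[1]), int(parts[2]), parts[3])
    if parts[0] == "S":
        start = int(parts[1])
        ref, alt = parts[2].split(">")
        subs = tuple((start + i, r, a) for i, (r, a) in enumerate(zip(ref, alt)))
        return RepairEvent("substitution", start, len(subs), sub_bases=subs)
    raise ValueError(f"cannot parse event {text!r}")


@dataclass(frozen=True)
class AlleleCall:
    """Classification of one distinct allele."""

    events: tuple[RepairEvent, ...]
    pattern: str
    mh_len: int = 0
    templated: bool = False
    read_count: int = 1
    allele_seq: str = ""


@dataclass
class OutcomeSpectrum:
    """Per-pattern counts and proportions for one sample."""

    counts: dict[str, int]
    proportions: dict[str, float]
    total_edited: int
    unedited: int
    unalignable: int
    editing_fraction: float
    empty: bool
    allele_table: list[AlleleCall] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Alignment and event extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentScoring:
    """Affine-gap global alignment scores and the alignability floor."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -8.0
    gap_extend: float = -1.0
    min_identity: float = 0.6


def _make_aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


class UnalignableReadError(ValueError):
    """Read identity to the reference fell below the configured floor."""


def align_read(
    read: str,
    locus: TargetLocus,
    scoring: AlignmentScoring | None = None,
) -> list[RepairEvent]:
    """Globally align ``read`` to the locus reference and emit repair events.

    Events are returned in reference order with indels left-normalized.
    Adjacent mismatches merge into a single substitution event.

    Raises
    ------
    UnalignableReadError
        If the fraction of matching columns falls below
        ``scoring.min_identity``.
    """
    scoring = scoring or AlignmentScoring()
    ref = locus.ref_seq.upper()
    read = read.upper()
    if read == ref:
        return []
    aligner = _make_aligner(scoring)
    alignment = aligner.align(ref, read)[0]
    ref_blocks, read_blocks = alignment.aligned

    events: list[RepairEvent] = []
    matches = 0
    columns = 0
    prev_ref_end = 0
    prev_read_end = 0
    for (rs, re), (qs, qe) in zip(ref_blocks, read_blocks):
        if rs > prev_ref_end:  # reference bases skipped -> deletion
            events.append(RepairEvent("deletion", prev_ref_end, rs - prev_ref_end))
            columns += rs - prev_ref_end
        if qs > prev_read_end:  # read bases unaccounted -> insertion
            events.append(
                RepairEvent("insertion", rs, qs - prev_read_end, read[prev_read_end:qs])
            )
            columns += qs - prev_read_end
        run_start = -1
        for i in range(re - rs):
            columns += 1
            if ref[rs + i] == read[qs + i]:
                matches += 1
                if run_start >= 0:
                    events.append(_sub_event(ref, read, rs, qs, run_start, i))
                    run_start = -1
            elif run_start < 0:
                run_start = i
        if run_start >= 0:
            events.append(_sub_event(ref, read, rs, qs, run_start, re - rs))
        prev_ref_end, prev_read_end = re, qe
    if len(ref) > prev_ref_end:
        events.append(RepairEvent("deletion", prev_ref_end, len(ref) - prev_ref_end))
        columns += len(ref) - prev_ref_end
    if len(read) > prev_read_end:
        events.append(
            RepairEvent("insertion", len(ref), len(read) - prev_read_end,
                        read[prev_read_end:])
        )
        columns += len(read) - prev_read_end

    if columns == 0 or matches / columns < scoring.min_identity:
        raise UnalignableReadError(
            f"identity {matches}/{columns} below floor {scoring.min_identity}"
        )
    events = [left_normalize(ev, ref) for ev in events]
    events.sort(key=lambda e: (e.start, e.kind))
    return events


def _sub_event(ref: str, read: str, rs: int, qs: int, i0: int, i1: int) -> RepairEvent:
    subs = tuple(
        (rs + i, ref[rs + i], read[qs + i]) for i in range(i0, i1)
    )
    return RepairEvent("substitution", rs + i0, i1 - i0, sub_bases=subs)


def apply_events(ref_seq: str, events: Sequence[RepairEvent]) -> str:
    """Reconstruct the edited sequence by applying ``events`` to ``ref_seq``.

    Events must be non-overlapping; they are applied in coordinate order.
    Used both by the read generator and by the alignment round-trip check.
    """
    out: list[str] = []
    pos = 0
    for ev in sorted(events, key=lambda e: (e.start, e.kind != "insertion")):
        if ev.start < pos:
            raise ValueError("overlapping events")
        out.append(ref_seq[pos:ev.start])
        pos = ev.start
        if ev.kind == "insertion":
            out.append(ev.inserted_seq)
        elif ev.kind == "deletion":
            pos += ev.length
        else:
            out.append("".join(b[2] for b in ev.sub_bases))
            pos += ev.length
    out.append(ref_seq[pos:])
    return "".join(out)


# ---------------------------------------------------------------------------
# Normalization and microhomology
# ---------------------------------------------------------------------------

def left_normalize(event: RepairEvent, ref_seq: str) -> RepairEvent:
    """Shift an indel to its leftmost placement producing the same allele.

    Deletions slide left while the base entering the deleted window from the
    left equals the base leaving it on the right; insertions rotate the
    inserted sequence the standard VCF way.  Substitutions are returned
    unchanged.  The operation is idempotent.
    """
    if event.kind == "deletion":
        start, L = event.start, event.length
        while start > 0 and ref_seq[start - 1] == ref_seq[start + L - 1]:
            start -= 1
        if start == event.start:
            return event
        return replace(event, start=start)
    if event.kind == "insertion":
        start, seq = event.start, event.inserted_seq
        while start > 0 and ref_seq[start - 1] == seq[-1]:
            seq = ref_seq[start - 1] + seq[:-1]
            start -= 1
        if start == event.start:
            return event
        return replace(event, start=start, inserted_seq=seq)
    return event


def detect_microhomology(deletion: RepairEvent, ref_seq: str) -> int:
    """Length of the junction microhomology of a left-normalized deletion.

    Returns the largest ``k`` such that the first ``k`` deleted bases equal
    the ``k`` bases immediately downstream of the deletion::

        ref[start : start+k] == ref[start+L : start+L+k]

    This equals the placement-ambiguity span of the deletion: an MMEJ
    junction retains one copy of the repeat shared by the two ends.
    Comparisons stop at the reference boundary.
    """
    if deletion.kind != "deletion":
        raise ValueError("detect_microhomology expects a deletion event")
    start, L = deletion.start, deletion.length
    n = len(ref_seq)
    k = 0
    while (start + k < start + L  # compare within the deleted span only
           and start + L + k < n
           and ref_seq[start + k] == ref_seq[start + L + k]):
        k += 1
    return k


def call_repair_events(
    events: Sequence[RepairEvent],
    cut_site: int,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> list[RepairEvent]:
    """Keep events whose span overlaps the cut-site window.

    The window is the closed coordinate interval
    ``[cut_site - window_bp, cut_site + window_bp]``.  Deletions and
    substitutions overlap it if any of their positions fall inside;
    insertions if their anchor coordinate does.
    """
    lo, hi = cut_site - window_bp, cut_site + window_bp
    kept = []
    for ev in events:
        if ev.kind == "insertion":
            if lo <= ev.start <= hi:
                kept.append(ev)
        else:
            if ev.start <= hi and ev.end - 1 >= lo:
                kept.append(ev)
    return kept


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _is_templated(ins: RepairEvent, ref_seq: str) -> bool:
    """Inserted sequence duplicates an equal-length flank of its anchor."""
    L, s = ins.length, ins.start
    left = ref_seq[max(0, s - L):s]
    right = ref_seq[s:s + L]
    return ins.inserted_seq in (left, right) and L > 0


def classify_allele(
    events: Sequence[RepairEvent],
    ref_seq: str,
    mh_min: int = DEFAULT_MH_MIN,
    read_count: int = 1,
    allele_seq: str = "",
) -> AlleleCall:
    """Assign one of the seven indel patterns (or Unedited) to an allele.

    ``events`` must already be left-normalized and restricted to the
    cut-site window.  Alleles with no events are Unedited; substitution-only
    alleles are Mut.  Otherwise the dominant indel (longest; ties favor the
    deletion) decides the class, with the MH/NonMH split at ``mh_min`` bp of
    junction microhomology and the small/large deletion boundary at
    ``SMALL_DEL_MAX`` bp.
    """
    events = tuple(sorted(events, key=lambda e: (e.start, e.kind)))
    if not events:
        return AlleleCall(events, UNEDITED, read_count=read_count,
                          allele_seq=allele_seq)
    indels = [e for e in events if e.kind != "substitution"]
    if not indels:
        return AlleleCall(events, "Mut", read_count=read_count,
                          allele_seq=allele_seq)
    # Dominant event: longest; tie -> deletion over insertion.
    dominant = max(indels, key=lambda e: (e.length, e.kind == "deletion"))
    templated = any(_is_templated(e, ref_seq) for e in indels
                    if e.kind == "insertion")
    if dominant.kind == "insertion":
        pattern = "1bp Ins" if dominant.length == 1 else "Large Ins"
        return AlleleCall(events, pattern, templated=templated,
                          read_count=read_count, allele_seq=allele_seq)
    mh_len = detect_microhomology(dominant, ref_seq)
    small = dominant.length <= SMALL_DEL_MAX
    mh = mh_len >= mh_min
    pattern = (
        ("MH Small Del" if mh else "NonMH Small Del") if small
        else ("MH Large Del" if mh else "NonMH Large Del")
    )
    return AlleleCall(events, pattern, mh_len=mh_len, templated=templated,
                      read_count=read_count, allele_seq=allele_seq)


def classify_reads(
    reads: Iterable[str],
    locus: TargetLocus,
    window_bp: int = DEFAULT_WINDOW_BP,
    mh_min: int = DEFAULT_MH_MIN,
    scoring: AlignmentScoring | None = None,
) -> OutcomeSpectrum:
    """Run the full per-read pipeline and summarize the outcome spectrum.

    Distinct alleles are aligned once and their read counts aggregated.
    Reads that fail the alignment identity floor, or that carry an N inside
    the cut-site window, are excluded and counted as unalignable.
    """
    ref = locus.ref_seq.upper()
    cut = locus.cut_site
    allele_counts = Counter(r.upper() for r in reads)
    calls: list[AlleleCall] = []
    unalignable = 0
    for seq, count in sorted(allele_counts.items(),
                             key=lambda kv: (-kv[1], kv[0])):
        try:
            events = align_read(seq, locus, scoring)
        except UnalignableReadError:
            unalignable += count
            continue
        windowed = call_repair_events(events, cut, window_bp)
        if any("N" in ev.inserted_seq
               or any(b[2] == "N" for b in ev.sub_bases)
               for ev in windowed):
            unalignable += count
            continue
        calls.append(classify_allele(windowed, ref, mh_min,
                                     read_count=count, allele_seq=seq))
    return summarize_spectrum(calls, unalignable=unalignable)


def summarize_spectrum(
    calls: Sequence[AlleleCall],
    unalignable: int = 0,
) -> OutcomeSpectrum:
    """Aggregate allele calls into per-pattern counts and proportions.

    Proportions are over edited patterns only; the Unedited class enters the
    editing fraction edited/(edited+unedited) instead.  A spectrum with zero
    edited reads is flagged ``empty`` and carries no proportions.
    """
    counts: dict[str, int] = {p: 0 for p in EDITED_PATTERNS}
    unedited = 0
    for call in calls:
        if call.pattern == UNEDITED:
            unedited += call.read_count
        else:
            counts[call.pattern] += call.read_count
    total_edited = sum(counts.values())
    empty = total_edited == 0
    proportions = (
        {} if empty
        else {p: c / total_edited for p, c in counts.items()}
    )
    denom = total_edited + unedited
    editing_fraction = total_edited / denom if denom else 0.0
    return OutcomeSpectrum(
        counts=counts,
        proportions=proportions,
        total_edited=total_edited,
        unedited=unedited,
        unalignable=unalignable,
        editing_fraction=editing_fraction,
        empty=empty,
        allele_table=list(calls),
    )


# ---------------------------------------------------------------------------
# Breakpoint profiling
# ---------------------------------------------------------------------------

def breakpoint_profile(
    calls: Sequence[AlleleCall],
    cut_site: int,
    pam_is_downstream: bool = True,
) -> tuple[dict[int, int], float]:
    """Histogram of deleted reference positions relative to the cut site.

    Returns ``(histogram, distal_proximal_ratio)`` where the histogram maps
    each position offset (position − cut_site; negative = 5' of the cut) to
    the number of deleted bases observed there, weighted by read count, and
    the ratio sums deleted bases on the PAM-distal side over the
    PAM-proximal side.  With a downstream (3') PAM the distal side is the
    5' side of the cut.  An all-distal profile yields ``inf``.
    """
    hist: Counter[int] = Counter()
    for call in calls:
        for ev in call.events:
            if ev.kind != "deletion":
                continue
            for pos in range(ev.start, ev.end):
                hist[pos - cut_site] += call.read_count
    # Offsets < 0 are 5' of the cut.
    upstream = sum(c for off, c in hist.items() if off < 0)
    downstream = sum(c for off, c in hist.items() if off >= 0)
    distal, proximal = (
        (upstream, downstream) if pam_is_downstream else (downstream, upstream)
    )
    ratio = distal / proximal if proximal else float("inf")
    return dict(hist), ratio
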