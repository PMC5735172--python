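"""3'-extremity mapping and non-templated tail calling.

A retained sense insert is matched exactly against the reference window of
its amplicon.  Inserts that do not match are trimmed from their 3' end one
nucleotide at a time, re-matching after each step, until a maximum of 30 nt
has been removed; the trimmed nucleotides at the first successful depth are
the candidate non-templated tail.  Two rejection rules then guard against
sequencing errors and polymorphisms masquerading as tails:

* second-nucleotide rule - if the second tail nucleotide equals the
  reference base two positions past the mapped end, the read is treated as
  a terminal mismatch followed by templated sequence and removed;
* homopolymer stretch filter - tails longer than 6, 10 and 15 nt are kept
  only if they contain at least 1, 2 and 3 stretches of AAA or TTT,
  respectively (non-overlapping, counted greedily left to right).

Ends mapping strictly upstream of the forward primer's 3' end are
discarded.  Coordinates are 1-based on the sense strand; raw position 1 is
the first reference nucleotide matching the forward primer, and a
per-amplicon offset converts raw ends to the reporting convention (for 5.8S
precursors, reported position 1 is the first nucleotide after the mature
5.8S 3' end; for the 5' ETS, the reported end equals the intermediate's
length from the P site).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import pandas as pd

from .synthetic_data import AmpliconTarget

__all__ = [
    "ReferenceIndex",
    "ThreePrimeCall",
    "map_exact",
    "call_three_prime",
    "stretch_filter",
    "count_stretches",
    "correct_coordinates",
    "call_inserts",
    "MAX_TRIM",
]

MAX_TRIM = 30
STRETCHES = ("AAA", "TTT")


@dataclass(frozen=True)
class ReferenceIndex:
    """Reference sequence plus the amplicon window it is searched in.

    The window runs from the amplicon anchor to ``window_length`` bases
    downstream (amplicons are short; restricting the window suppresses
    spurious matches elsewhere in the rRNA repeat).
    """

    sequence: str
    target: AmpliconTarget
    window_length: int = 600

    def __post_init__(self) -> None:
        anchor = self.target.anchor_position
        if anchor > len(self.sequence):
            raise ValueError("anchor_position outside the reference")
        if self.sequence[anchor - 1 :].startswith(self.target.search_seq) is False:
            raise ValueError("reference does not carry the search sequence at the anchor")

    @cached_property
    def window(self) -> str:
        start = self.target.anchor_position - 1
        return self.sequence[start : start + self.window_length]

    @property
    def raw_plus_one(self) -> int:
        return self.target.anchor_position

    @property
    def report_offset(self) -> int:
        return self.target.plus_one_offset

    @property
    def primer_end_raw(self) -> int:
        return len(self.target.search_seq)


@dataclass
class ThreePrimeCall:
    read_id: str
    target: str
    end_reported: int | None
    tail_seq: str
    status: str  # unmodified / modified / discarded
    discard_reason: str = ""  # unmapped_after_30, second_nt_match,
    #                            stretch_filter, upstream_of_primer

    @property
    def tail_len(self) -> int:
        return len(self.tail_seq)


def map_exact(sense_seq: str, ref: ReferenceIndex) -> int | None:
    """Raw coordinate of the insert's last base if it occurs exactly once
    in the amplicon window; None if absent or ambiguous (multiple exact
    placements are surfaced as no-match rather than silently resolved)."""
    if not sense_seq:
        return None
    window = ref.window
    first = window.find(sense_seq)
    if first < 0:
        return None
    if window.find(sense_seq, first + 1) >= 0:
        return None
    return first + len(sense_seq)


def count_stretches(tail_seq: str, mode: str = "greedy") -> int:
    """Number of AAA/TTT stretches in a tail.

    ``greedy``: non-overlapping occurrences over the union pattern set,
    counted left to right (so "AAAA" is one stretch); for fixed-length
    patterns this greedy scan attains the maximum non-overlapping count.
    ``overlapping``: every starting position counts.
    """
    if mode == "overlapping":
        return sum(
            1 for i in range(len(tail_seq) - 2) if tail_seq[i : i + 3] in STRETCHES
        )
    if mode != "greedy":
        raise ValueError(f"unknown stretch mode {mode!r}")
    n = 0
    i = 0
    while i + 3 <= len(tail_seq):
        if tail_seq[i : i + 3] in STRETCHES:
            n += 1
            i += 3
        else:
            i += 1
    return n


def _required_stretches(tail_length: int) -> int:
    # "longer than 6, 10 and 15 nt" read strictly: thresholds at >=7, >=11, >=16
    if tail_length <= 6:
        return 0
    if tail_length <= 10:
        return 1
    if tail_length <= 15:
        return 2
    return 3


def stretch_filter(tail_seq: str, mode: str = "greedy") -> bool:
    """Keep/drop decision of the homopolymer stretch filter."""
    return count_stretches(tail_seq, mode=mode) >= _required_stretches(len(tail_seq))


def correct_coordinates(raw_end: int, ref: ReferenceIndex) -> int:
    """Raw 3'-end coordinate converted to the reporting convention."""
    return raw_end + ref.report_offset


def call_three_prime(
    sense_seq: str,
    ref: ReferenceIndex,
    read_id: str = "",
    max_trim: int = MAX_TRIM,
    stretch_mode: str = "greedy",
) -> ThreePrimeCall:
    """Map one insert and call its 3' extremity and tail.

    Minimal trim depth wins; the trimmed bases at that depth are the tail,
    so trim depth k implies tail length exactly k.
    """
    if not sense_seq:
        raise ValueError("empty insert")
    name = ref.target.name
    for k in range(0, min(max_trim, len(sense_seq) - 1) + 1):
        core = sense_seq[: len(sense_seq) - k]
        raw_end = map_exact(core, ref)
        if raw_end is None:
            continue
        tail = sense_seq[len(sense_seq) - k :]
        if raw_end < ref.primer_end_raw:
            return ThreePrimeCall(read_id, name, None, tail, "discarded", "upstream_of_primer")
        if k == 0:
            return ThreePrimeCall(
                read_id, name, correct_coordinates(raw_end, ref), "", "unmodified"
            )
        if len(tail) >= 2:
            second_idx = raw_end + 1  # 0-based window index of raw_end + 2
            if second_idx < len(ref.window) and ref.window[second_idx] == tail[1]:
                return ThreePrimeCall(
                    read_id, name, None, tail, "discarded", "second_nt_match"
                )
        if not stretch_filter(tail, mode=stretch_mode):
            return ThreePrimeCall(read_id, name, None, tail, "discarded", "stretch_filter")
        return ThreePrimeCall(
            read_id, name, correct_coordinates(raw_end, ref), tail, "modified"
        )
    return ThreePrimeCall(read_id, name, None, "", "discarded", "unmapped_after_30")


def call_inserts(
    inserts,
    references: dict[str, ReferenceIndex] | ReferenceIndex,
    max_trim: int = MAX_TRIM,
    stretch_mode: str = "greedy",
) -> tuple[pd.DataFrame, dict]:
    """Call every retained insert against its amplicon's reference index.

    ``inserts`` is an iterable of ProcessedInsert (or any object with
    read_id/target/sense_seq).  Returns the calls table and a status-count
    summary.
    """
    if isinstance(references, ReferenceIndex):
        references = {references.target.name: references}
    rows = []
    counts: dict[str, int] = {}
    for ins in inserts:
        if getattr(ins, "drop_reason", ""):
            continue
        ref = references[ins.target]
        call = call_three_prime(
            ins.sense_seq, ref, read_id=ins.read_id,
            max_trim=max_trim, stretch_mode=stretch_mode,
        )
        key = call.discard_reason if call.status == "discarded" else call.status
        counts[key] = counts.get(key, 0) + 1
        rows.append(
            {
                "read_id": call.read_id,
                "target": call.target,
                "end_reported": call.end_reported,
                "tail_seq": call.tail_seq,
                "tail_len": call.tail_len,
                "status": call.status,
                "discard_reason": call.discard_reason,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "read_id", "target", "end_reported", "tail_seq",
            "tail_len", "status", "discard_reason",
        ],
    )
    return frame, counts
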