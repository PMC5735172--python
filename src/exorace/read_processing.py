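"""Raw read-pair processing: deduplication, target assignment, adapter and
primer stripping, length filtering.

Stage order is fixed and mirrors the 3'RACE-seq protocol:

1. deduplicate on (read 1, read-2 cycles 1-15), i.e. insert + randomized
   adapter bases;
2. assign each read 1 to an amplicon by searching the gene-specific
   sequence, allowing one mismatch;
3. require the 5-nt delimiter at read-2 cycles 16-20 (positional check by
   default; a substring-search dialect is available);
4. strip the randomized bases and delimiter, reverse complement into sense
   orientation, and remove any read-through into the forward PCR primer;
5. drop inserts shorter than 20 nt.

Counts are conserved: every input pair is either retained or attributed to
exactly one drop reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .synthetic_data import AdapterSpec, AmpliconTarget, revcomp

__all__ = [
    "ReadPair",
    "ProcessedInsert",
    "AmbiguousTargetError",
    "deduplicate",
    "assign_target",
    "check_delimiter",
    "strip_and_orient",
    "length_filter",
    "process_read_pairs",
    "read_paired_fastq",
    "inserts_to_frame",
    "load_amplicon_panel",
]

logger = logging.getLogger("exorace")

MIN_INSERT_LENGTH = 20


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    seq1: str
    seq2: str


@dataclass
class ProcessedInsert:
    read_id: str
    target: str = ""
    umi: str = ""
    sense_seq: str = ""
    drop_reason: str = ""  # "", duplicate, no_target, no_delimiter, too_short


class AmbiguousTargetError(ValueError):
    """Read 1 matches more than one panel target; the panel search
    sequences should make this impossible, so it is surfaced."""


def deduplicate(pairs: list[ReadPair]) -> list[ReadPair]:
    """Keep the first read pair per (seq1, seq2[1..15]) key.

    Base qualities are unused, so the first occurrence is an equivalent and
    deterministic representative.  Pairs whose read 2 is shorter than 15 nt
    have no defined key and are discarded (logged).
    """
    seen: set[tuple[str, str]] = set()
    kept: list[ReadPair] = []
    n_undefined = 0
    for pair in pairs:
        if len(pair.seq2) < 15:
            n_undefined += 1
            continue
        key = (pair.seq1, pair.seq2[:15])
        if key not in seen:
            seen.add(key)
            kept.append(pair)
    if n_undefined:
        logger.warning(
            "%d read pairs discarded: read 2 shorter than 15 nt, "
            "duplicate key undefined",
            n_undefined,
        )
    return kept


def _hamming_within(a: str, b: str, limit: int) -> bool:
    """True if Hamming(a, b) <= limit; N never matches."""
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > limit:
                return False
    return True


def assign_target(
    seq1: str, panel: list[AmpliconTarget], max_mismatch: int = 1
) -> str | None:
    """Name of the panel target whose search sequence occurs in read 1 with
    at most ``max_mismatch`` substitutions, or None.

    Matching is position-independent (any offset) and Hamming-only: the
    protocol allows one mismatch, and indels are not modelled.
    """
    hits: list[str] = []
    for target in panel:
        s = target.search_seq
        if s in seq1:
            hits.append(target.name)
            continue
        if max_mismatch > 0 and len(seq1) >= len(s):
            for off in range(len(seq1) - len(s) + 1):
                if _hamming_within(seq1[off : off + len(s)], s, max_mismatch):
                    hits.append(target.name)
                    break
    if len(hits) > 1:
        raise AmbiguousTargetError(
            f"read matches several targets: {sorted(set(hits))}"
        )
    return hits[0] if hits else None


def check_delimiter(
    seq2: str, adapter: AdapterSpec, mode: str = "positional"
) -> bool:
    """Delimiter check on read 2.

    The adapter architecture fixes the delimiter at cycles 16-20, right
    after the 15 randomized bases, so the default check is positional and
    exact.  ``mode="search"`` restores a literal anywhere-in-read test.
    """
    if mode == "positional":
        return len(seq2) >= 20 and seq2[15:20] == adapter.delimiter
    if mode == "search":
        return adapter.delimiter in seq2
    raise ValueError(f"unknown delimiter mode {mode!r}")


def strip_and_orient(seq2: str, adapter: AdapterSpec, target: AmpliconTarget) -> str:
    """Adapter-stripped, sense-oriented insert from read 2.

    Cycles 1-20 (randomized bases + delimiter) are removed and the
    remainder reverse complemented.  If the forward primer-derived search
    sequence occurs in the sense insert - short amplicons make read 2 run
    through the 5' PCR primer - everything up to and including the primer
    copy is removed, so the insert begins at the first templated base after
    the primer.  The primer match must be exact; no mismatch allowance is
    given for this removal.
    """
    sense = revcomp(seq2[20:])
    idx = sense.find(target.search_seq)
    if idx >= 0:
        sense = sense[idx + len(target.search_seq):]
    return sense


def length_filter(sense_seq: str, min_len: int = MIN_INSERT_LENGTH) -> bool:
    """Keep inserts of at least ``min_len`` nt ("shorter than 20 nt" reads
    are excluded, so a 20-nt insert is kept)."""
    return len(sense_seq) >= min_len


@dataclass
class RunSummary:
    input_pairs: int = 0
    undeduplicatable: int = 0
    duplicates: int = 0
    unique_pairs: int = 0
    no_target: int = 0
    no_delimiter: int = 0
    too_short: int = 0
    retained: int = 0
    per_target_retained: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "input_pairs": self.input_pairs,
            "undeduplicatable": self.undeduplicatable,
            "duplicates": self.duplicates,
            "unique_pairs": self.unique_pairs,
            "no_target": self.no_target,
            "no_delimiter": self.no_delimiter,
            "too_short": self.too_short,
            "retained": self.retained,
            "per_target_retained": dict(self.per_target_retained),
        }


def process_read_pairs(
    pairs: list[ReadPair],
    panel: list[AmpliconTarget],
    adapter: AdapterSpec | None = None,
    delimiter_mode: str = "positional",
    min_len: int = MIN_INSERT_LENGTH,
) -> tuple[list[ProcessedInsert], RunSummary]:
    """Run all stages in order and return retained inserts plus counts.

    Only retained inserts are returned; the summary attributes every input
    pair to retained or exactly one drop reason.
    """
    adapter = adapter or AdapterSpec()
    summary = RunSummary(input_pairs=len(pairs))
    summary.undeduplicatable = sum(1 for p in pairs if len(p.seq2) < 15)
    unique = deduplicate(pairs)
    summary.unique_pairs = len(unique)
    summary.duplicates = len(pairs) - summary.undeduplicatable - len(unique)

    inserts: list[ProcessedInsert] = []
    for pair in unique:
        name = assign_target(pair.seq1, panel)
        if name is None:
            summary.no_target += 1
            continue
        if not check_delimiter(pair.seq2, adapter, mode=delimiter_mode):
            summary.no_delimiter += 1
            continue
        target = next(t for t in panel if t.name == name)
        sense = strip_and_orient(pair.seq2, adapter, target)
        if not length_filter(sense, min_len=min_len):
            summary.too_short += 1
            continue
        summary.retained += 1
        summary.per_target_retained[name] = summary.per_target_retained.get(name, 0) + 1
        inserts.append(
            ProcessedInsert(
                read_id=pair.read_id,
                target=name,
                umi=pair.seq2[:15],
                sense_seq=sense,
            )
        )
    return inserts, summary


def read_paired_fastq(r1_path: str, r2_path: str) -> list[ReadPair]:
    """Load paired FASTQ files (read order must match)."""
    from Bio import SeqIO

    pairs = []
    for rec1, rec2 in zip(
        SeqIO.parse(r1_path, "fastq"), SeqIO.parse(r2_path, "fastq"), strict=True
    ):
        pairs.append(ReadPair(rec1.id, str(rec1.seq).upper(), str(rec2.seq).upper()))
    return pairs


def inserts_to_frame(inserts: list[ProcessedInsert]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "read_id": i.read_id,
                "target": i.target,
                "umi": i.umi,
                "sense_seq": i.sense_seq,
                "drop_reason": i.drop_reason,
            }
            for i in inserts
        ],
        columns=["read_id", "target", "umi", "sense_seq", "drop_reason"],
    )


def load_amplicon_panel(path: str) -> list[AmpliconTarget]:
    """Panel TSV with columns name, search_seq, anchor_position and
    optionally plus_one_offset."""
    frame = pd.read_csv(path, sep="\t")
    targets = []
    for _, row in frame.iterrows():
        targets.append(
            AmpliconTarget(
                name=str(row["name"]),
                search_seq=str(row["search_seq"]),
                anchor_position=int(row["anchor_position"]),
                plus_one_offset=int(row.get("plus_one_offset", 0) or 0),
            )
        )
    return targets
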