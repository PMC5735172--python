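"""Ground-truth simulation of 3'RACE-seq amplicon libraries.

The emulated library architecture follows the adapter-ligation 3'RACE
protocol used for mapping 3' extremities of rRNA maturation intermediates:
a DNA adapter consisting of a 5-nt delimiter, 15 randomized nucleotides
(a de facto unique molecular identifier) and a 22-nt Illumina-complementary
segment is ligated to the RNA 3' end.  After RT-PCR with a gene-specific
forward primer, libraries are paired-end sequenced with a 41 x 101 cycle
setting: read 1 covers the first 41 nt of the sense amplicon, read 2 starts
on the adapter side and reads the randomized bases (cycles 1-15), the
delimiter (cycles 16-20) and then the reverse complement of the insert,
i.e. of [templated sequence up to the molecule's true 3' end + any
non-templated tail].  When the insert is short, read 2 runs through the
reverse complement of the forward primer and beyond.

Every simulated molecule carries a ground-truth record (true 3' end, true
tail, UMI, PCR copy number) together with the *expected fate* of that
molecule in the downstream pipeline, so that parameter recovery can be
verified molecule by molecule.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AdapterSpec",
    "AmpliconTarget",
    "SimulationConfig",
    "GroundTruthMolecule",
    "SEARCH_SEQUENCES",
    "CANONICAL_ETS_PEAKS",
    "revcomp",
    "generate_reference",
    "simulate_molecules",
    "render_read_pairs",
    "simulate_library",
    "write_fastq",
    "default_end_distribution",
    "default_tail_length_distribution",
    "default_tail_composition",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
BASES = "ACGT"

#: Gene-specific sequences searched in read 1 to assign the amplicon, one
#: per target: the 5' ETS P-P1 fragments, the mature 5.8S rRNA, and 5.8S
#: rRNA precursors.
SEARCH_SEQUENCES: dict[str, str] = {
    "ets_pp1": "ATCTCGCGCTTGTACGGC",
    "r58S_mature": "TTCTGGCCGAGGGCACGTCTG",
    "r58S_precursor": "TCTGCCTGGGTGTCACAA",
}

#: The four major P-P1 degradation intermediates, named by their length in
#: nucleotides from the P site (+1 = first nucleotide of the P-P' fragment).
CANONICAL_ETS_PEAKS = (161, 168, 176, 186)

DEFAULT_DELIMITER = "CTGAC"
# 22-nt segment complementary to the reverse Illumina primer (TruSeq-like).
DEFAULT_LINKER = "AGATCGGAAGAGCACACGTCTG"
# Fixed outer context 5' of the simulated reference; read 2 runs into it
# when the amplicon is much shorter than the 81 insert-side cycles.
UPSTREAM_HANDLE = "GTTCAGAGTTCTACAGTCCGACGAT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_probability_map(name: str, mapping: Mapping, tol: float = 1e-9) -> None:
    if not mapping:
        raise ValueError(f"{name} must be non-empty")
    total = float(sum(mapping.values()))
    if any(v < 0 for v in mapping.values()):
        raise ValueError(f"{name} has negative probabilities")
    if abs(total - 1.0) > tol:
        raise ValueError(f"{name} sums to {total}, expected 1")


@dataclass(frozen=True)
class AdapterSpec:
    """3' adapter layout: 5-nt delimiter, 15 randomized nt, 22-nt linker."""

    delimiter: str = DEFAULT_DELIMITER
    umi_length: int = 15
    tail_side_linker: str = DEFAULT_LINKER

    def __post_init__(self) -> None:
        if len(self.delimiter) != 5:
            raise ValueError("delimiter must be 5 nt")
        if self.umi_length != 15:
            raise ValueError("umi_length must be 15")
        if len(self.tail_side_linker) != 22:
            raise ValueError("tail_side_linker must be 22 nt")
        for part in (self.delimiter, self.tail_side_linker):
            if set(part) - set(BASES):
                raise ValueError("adapter sequences must be over A/C/G/T")


@dataclass(frozen=True)
class AmpliconTarget:
    """One amplicon of the panel.

    ``search_seq`` is the forward-primer-derived sequence looked up in
    read 1; ``anchor_position`` is the 1-based reference coordinate of its
    first nucleotide.  Raw 3'-end coordinates count from the anchor
    (raw position 1 = anchor); ``plus_one_offset`` converts raw to the
    reporting convention (e.g. for 5.8S precursors, reported position 1 is
    the first nucleotide after the mature 5.8S 3' end).
    """

    name: str
    search_seq: str
    anchor_position: int
    plus_one_offset: int = 0

    def __post_init__(self) -> None:
        if not self.search_seq or len(self.search_seq) > 41:
            raise ValueError("search_seq must be 1-41 nt")
        if self.anchor_position < 1:
            raise ValueError("anchor_position must be >= 1")


def default_end_distribution() -> dict[int, float]:
    """Equal-weight mixture over the four major P-P1 intermediates."""
    return {p: 0.25 for p in CANONICAL_ETS_PEAKS}


def default_tail_length_distribution(decay: float = 0.65, max_len: int = 30) -> dict[int, float]:
    """Truncated geometric tail-length distribution over 1..max_len.

    The default decay puts ~35% of tails at a single nucleotide, matching
    the observation that many 3' mismatches are single-nucleotide.
    """
    raw = {k: decay ** (k - 1) for k in range(1, max_len + 1)}
    total = sum(raw.values())
    return {k: v / total for k, v in raw.items()}


def default_tail_composition() -> dict[str, float]:
    """A-rich tail composition (85% A), as seen for bona fide 3' tails."""
    return {"A": 0.85, "C": 0.05, "G": 0.05, "T": 0.05}


@dataclass
class SimulationConfig:
    reference: str
    target: AmpliconTarget
    n_molecules: int = 10_000
    end_distribution: dict[int, float] = field(default_factory=default_end_distribution)
    tail_probability: float = 0.3
    tail_length_distribution: dict[int, float] = field(
        default_factory=default_tail_length_distribution
    )
    tail_composition: dict[str, float] = field(default_factory=default_tail_composition)
    duplication_mean: float = 1.5
    error_rate: float = 0.0
    read1_length: int = 41
    read2_length: int = 101
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 0:
            raise ValueError("n_molecules must be >= 0")
        if not 0.0 <= self.tail_probability <= 1.0:
            raise ValueError("tail_probability must be in [0, 1]")
        if self.duplication_mean < 1.0:
            raise ValueError("duplication_mean must be >= 1")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.read1_length < 1 or self.read2_length < 21:
            raise ValueError("read lengths too small for the library layout")
        _check_probability_map("end_distribution", self.end_distribution)
        _check_probability_map("tail_length_distribution", self.tail_length_distribution)
        _check_probability_map("tail_composition", self.tail_composition)
        if any(not 1 <= k <= 30 for k in self.tail_length_distribution):
            raise ValueError("tail lengths must be in 1..30")
        if set(self.tail_composition) - set(BASES):
            raise ValueError("tail_composition bases must be A/C/G/T")
        anchor = self.target.anchor_position
        for pos in self.end_distribution:
            raw = pos - self.target.plus_one_offset
            if raw < 1:
                raise ValueError(f"end position {pos} lies upstream of the anchor")
            if anchor - 1 + raw > len(self.reference):
                raise ValueError(f"end position {pos} lies beyond the reference")


@dataclass
class GroundTruthMolecule:
    molecule_id: int
    true_end_position: int  # reporting-convention coordinate
    true_tail: str          # may be empty, <= 30 nt
    umi: str                # 15 nt
    n_copies: int = 1

    def __post_init__(self) -> None:
        if len(self.true_tail) > 30:
            raise ValueError("true_tail longer than 30 nt")
        if len(self.umi) != 15:
            raise ValueError("umi must be 15 nt")
        if self.n_copies < 1:
            raise ValueError("n_copies must be >= 1")


def generate_reference(
    length: int,
    target_name: str = "ets_pp1",
    seed: int = 0,
    protected_ends: Sequence[int] | None = None,
) -> tuple[str, AmpliconTarget]:
    """Random reference with exactly one planted occurrence of the target
    search sequence.

    ``protected_ends`` are raw 3'-end coordinates (relative to the anchor)
    whose two downstream reference bases are fixed to C and G.  Real peak
    positions sit in a fixed sequence context; fixing a non-A context keeps
    A-rich simulated tails distinguishable from templated sequence, so
    ground-truth recovery is well defined at the canonical peaks.  Defaults
    to the four major P-P1 positions for the 5' ETS target.
    """
    try:
        search = SEARCH_SEQUENCES[target_name]
    except KeyError:
        raise ValueError(f"unknown target {target_name!r}") from None
    if length < len(search) + 60:
        raise ValueError(
            f"reference length {length} too small; need >= {len(search) + 60}"
        )
    anchor = 21  # guaranteed to fit: length - len(search) - 39 >= 21
    if protected_ends is None:
        protected_ends = CANONICAL_ETS_PEAKS if target_name == "ets_pp1" else ()
    rng = np.random.default_rng(seed)
    for _ in range(100):
        seq = list(rng.choice(list(BASES), size=length))
        seq[anchor - 1 : anchor - 1 + len(search)] = list(search)
        for end in protected_ends:
            for offset, base in ((0, "C"), (1, "G")):
                idx = anchor - 1 + end + offset  # 0-based index of raw end+1, end+2
                if anchor - 1 + len(search) <= idx < length:
                    seq[idx] = base
        ref = "".join(seq)
        if ref.count(search) == 1:
            return ref, AmpliconTarget(target_name, search, anchor)
    raise RuntimeError("could not plant a unique search sequence")


def simulate_molecules(config: SimulationConfig) -> list[GroundTruthMolecule]:
    """Draw ground-truth molecules from the configured mixture model."""
    n = config.n_molecules
    rng = np.random.default_rng(config.seed)
    if n == 0:
        return []
    end_pos = np.array(sorted(config.end_distribution))
    end_p = np.array([config.end_distribution[p] for p in end_pos], dtype=float)
    end_p = end_p / end_p.sum()
    ends = rng.choice(end_pos, size=n, p=end_p)

    tailed = rng.random(n) < config.tail_probability
    lens = np.array(sorted(config.tail_length_distribution))
    len_p = np.array([config.tail_length_distribution[k] for k in lens], dtype=float)
    len_p = len_p / len_p.sum()
    tail_lengths = np.where(tailed, rng.choice(lens, size=n, p=len_p), 0)

    comp_bases = sorted(config.tail_composition)
    comp_p = np.array([config.tail_composition[b] for b in comp_bases], dtype=float)
    comp_p = comp_p / comp_p.sum()
    total_tail_nt = int(tail_lengths.sum())
    pool = rng.choice(list(comp_bases), size=max(total_tail_nt, 1), p=comp_p)

    umis = rng.integers(0, 4, size=(n, 15))
    copies = 1 + rng.poisson(max(config.duplication_mean - 1.0, 0.0), size=n)

    molecules: list[GroundTruthMolecule] = []
    cursor = 0
    base_arr = np.array(list(BASES))
    umi_strings = ["".join(row) for row in base_arr[umis]]
    for i in range(n):
        L = int(tail_lengths[i])
        tail = "".join(pool[cursor : cursor + L])
        cursor += L
        molecules.append(
            GroundTruthMolecule(
                molecule_id=i,
                true_end_position=int(ends[i]),
                true_tail=tail,
                umi=umi_strings[i],
                n_copies=int(copies[i]),
            )
        )
    return molecules


def _pad_or_trim(seq: str, length: int, pad_char: str = "G") -> str:
    if len(seq) >= length:
        return seq[:length]
    return seq + pad_char * (length - len(seq))


def _predict_fate(
    reference: str,
    target: AmpliconTarget,
    raw_end: int,
    tail: str,
    sense_window: str,
    min_len: int = 20,
    max_trim: int = 30,
) -> tuple[int | None, str, str]:
    """Expected downstream call for an error-free, non-duplicated read.

    Derived analytically from the calling rules: the minimal-trim mapping is
    equivalent to absorbing the longest tail prefix that matches the
    reference continuation into the templated region, after which the
    second-nucleotide rule and the homopolymer stretch filter apply.
    Returns (expected reported end, expected tail, fate), where fate is one
    of retained / shifted / too_short / second_nt_match / stretch_filter /
    upstream_of_primer / unmapped_after_30.
    """
    from .tail_mapper import stretch_filter  # shared rule, tested independently

    anchor = target.anchor_position
    s = sense_window
    idx = s.find(target.search_seq)
    if idx >= 0:
        s = s[idx + len(target.search_seq):]
    if len(s) < min_len:
        return None, "", "too_short"

    end, t = raw_end, tail
    while t:
        nxt = anchor - 1 + end  # 0-based index of raw position end+1
        if nxt < len(reference) and reference[nxt] == t[0]:
            end += 1
            t = t[1:]
        else:
            break
    if len(t) > max_trim:
        return None, t, "unmapped_after_30"
    if end < len(target.search_seq):
        return None, t, "upstream_of_primer"
    if t:
        if len(t) >= 2:
            nxt2 = anchor + end  # 0-based index of raw position end+2
            if nxt2 < len(reference) and reference[nxt2] == t[1]:
                return end + target.plus_one_offset, t, "second_nt_match"
        if not stretch_filter(t):
            return end + target.plus_one_offset, t, "stretch_filter"
    reported = end + target.plus_one_offset
    shifted = (end != raw_end) or (t != tail)
    return reported, t, "shifted" if shifted else "retained"


def render_read_pairs(
    molecules: Sequence[GroundTruthMolecule],
    config: SimulationConfig,
    adapter: AdapterSpec | None = None,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], pd.DataFrame]:
    """Render paired reads plus the per-read truth table.

    Returns (read-1 records, read-2 records, truth table); records are
    (read_id, sequence) tuples in input order.  The truth table carries one
    row per read pair and joins molecule ids to read ids; expected_* columns
    describe the call the pipeline should produce for the molecule's
    deduplication representative at error_rate 0 (sequencing errors make
    fates approximate).
    """
    adapter = adapter or AdapterSpec()
    target = config.target
    ref = config.reference
    anchor = target.anchor_position
    rng = np.random.default_rng(config.seed + 1)
    ins_cycles = config.read2_length - 20

    reads1: list[tuple[str, str]] = []
    reads2: list[tuple[str, str]] = []
    rows: list[dict] = []
    seen_keys: set[tuple[str, str]] = set()

    for mol in molecules:
        raw_end = mol.true_end_position - target.plus_one_offset
        if raw_end < 1:
            raise ValueError(
                f"molecule {mol.molecule_id}: true end upstream of the anchor"
            )
        abs_end = anchor - 1 + raw_end
        if abs_end > len(ref):
            raise ValueError(
                f"molecule {mol.molecule_id}: true end beyond the reference"
            )
        amplicon = ref[anchor - 1 : abs_end] + mol.true_tail
        read1 = _pad_or_trim(
            amplicon + adapter.delimiter + mol.umi + adapter.tail_side_linker,
            config.read1_length,
        )
        template = UPSTREAM_HANDLE + ref[:abs_end] + mol.true_tail
        sense_window = template[-ins_cycles:]
        read2 = _pad_or_trim(
            mol.umi + adapter.delimiter + revcomp(template), config.read2_length
        )

        key = (read1, mol.umi)
        if key in seen_keys:
            exp_end: int | None = None
            exp_tail, fate = "", "umi_collision"
        else:
            seen_keys.add(key)
            exp_end, exp_tail, fate = _predict_fate(
                ref, target, raw_end, mol.true_tail, sense_window
            )
        for c in range(mol.n_copies):
            read_id = f"M{mol.molecule_id}.{c}"
            reads1.append((read_id, _mutate(read1, config.error_rate, rng)))
            reads2.append((read_id, _mutate(read2, config.error_rate, rng)))
            rows.append(
                {
                    "molecule_id": mol.molecule_id,
                    "read_id": read_id,
                    "target": target.name,
                    "true_end": mol.true_end_position,
                    "true_tail": mol.true_tail,
                    "umi": mol.umi,
                    "n_copies": mol.n_copies,
                    "expected_end": exp_end,
                    "expected_tail": exp_tail,
                    "expected_fate": fate,
                }
            )
    truth = pd.DataFrame(
        rows,
        columns=[
            "molecule_id",
            "read_id",
            "target",
            "true_end",
            "true_tail",
            "umi",
            "n_copies",
            "expected_end",
            "expected_tail",
            "expected_fate",
        ],
    )
    return reads1, reads2, truth


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0.0:
        return seq
    hits = np.flatnonzero(rng.random(len(seq)) < error_rate)
    if hits.size == 0:
        return seq
    out = list(seq)
    for i in hits:
        choices = [b for b in BASES if b != out[i]]
        out[i] = choices[int(rng.integers(0, 3))]
    return "".join(out)


def simulate_library(
    config: SimulationConfig, adapter: AdapterSpec | None = None
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], pd.DataFrame]:
    """Convenience wrapper: simulate molecules and render their read pairs."""
    molecules = simulate_molecules(config)
    return render_read_pairs(molecules, config, adapter)


def write_fastq(records: Iterable[tuple[str, str]], path: str) -> None:
    """Write (read_id, sequence) records as FASTQ with constant 'I' quality.

    Base qualities are never used by the pipeline.  Gzip output is selected
    by a .gz suffix.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for rid, seq in records:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
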