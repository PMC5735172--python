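"""RRP41 catalytic-residue conservation calls and sequence-logo information
content.

The phosphorolytic activity of RNase PH-type exoribonucleases depends on a
small set of catalytic-pocket residues.  On the Arabidopsis RRP41
reference these are the phosphate-coordination pentapeptide DGGTR (ending
at R131, followed by S132) and the magnesium-coordinating aspartate D174;
mutating R131/S132/D174 to mimic the degenerate motif context of the
inactive human RRP41 (GGTYAA) abolishes activity.  An orthologue is called

* ``active``   - every critical panel position matches exactly;
* ``partial``  - critical positions deviate only by substitutions with
  similar chemical properties (e.g. DGGVK for DGGTR);
* ``inactive`` - at least one critical position carries a dissimilar
  residue, or no motif-like window is found.

Per-column sequence-logo information content is computed in bits as
log2(20) minus the Shannon entropy of the observed amino-acid frequencies;
gaps are excluded from the frequencies (columns with >50% gaps are
flagged) and no small-sample correction is applied unless requested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PanelPosition",
    "ResiduePanel",
    "ActivityCall",
    "default_panel",
    "locate_pi_motif",
    "classify_activity",
    "classify_alignment",
    "column_information",
    "logo_matrix",
    "summarize_groups",
    "synthetic_orthologue_set",
    "MAX_BITS",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHARS = set("-.")
MAX_BITS = math.log2(20)


@dataclass(frozen=True)
class PanelPosition:
    """One expected residue of the catalytic-pocket panel.

    ``offset`` is relative to the first residue of the Pi motif (0-4 are
    the motif itself); ``reference_position`` is the 1-based coordinate in
    the Arabidopsis RRP41 sequence.  ``allowed`` lists conservative
    substitutions compatible with a partially conserved verdict;
    non-critical positions are recorded as evidence but never demote the
    verdict.
    """

    label: str
    role: str  # Pi / Mg / RNA
    offset: int
    expected: str
    allowed: frozenset[str] = frozenset()
    critical: bool = True
    reference_position: int | None = None


@dataclass(frozen=True)
class ResiduePanel:
    positions: tuple[PanelPosition, ...]
    motif_length: int = 5
    reference_motif_start: int = 127  # D of DGGTR in Arabidopsis RRP41

    @property
    def motif_positions(self) -> tuple[PanelPosition, ...]:
        return tuple(p for p in self.positions if 0 <= p.offset < self.motif_length)

    @property
    def pi_motif(self) -> str:
        return "".join(p.expected for p in sorted(self.motif_positions, key=lambda p: p.offset))


def default_panel() -> ResiduePanel:
    """Best-effort reconstruction of the catalytic-pocket panel.

    Only positions the source material pins down are critical: the DGGTR
    motif and the catalytic aspartate D174.  S132 varies between active
    orthologues (mosses and worts) and is recorded but non-critical.  The
    RNA-binding set is left empty by default and is user-editable via the
    panel TSV.
    """
    motif = "DGGTR"
    allowed = {
        0: frozenset("E"),       # D -> E acidic
        1: frozenset(),          # G: glycine is structurally unique
        2: frozenset(),
        3: frozenset({"S", "V"}),  # T: small-polar S or isosteric V (DGGVK)
        4: frozenset({"K", "H"}),  # R: basic
    }
    positions = [
        PanelPosition(
            label=f"{motif[i]}{127 + i}",
            role="Pi",
            offset=i,
            expected=motif[i],
            allowed=allowed[i],
            reference_position=127 + i,
        )
        for i in range(5)
    ]
    positions.append(
        PanelPosition(
            label="S132", role="Pi", offset=5, expected="S",
            allowed=frozenset({"T", "A"}), critical=False, reference_position=132,
        )
    )
    positions.append(
        PanelPosition(
            label="D174", role="Mg", offset=47, expected="D",
            allowed=frozenset("E"), critical=True, reference_position=174,
        )
    )
    return ResiduePanel(tuple(positions))


@dataclass
class ActivityCall:
    species_id: str
    verdict: str  # active / partial / inactive
    motif_observed: str = ""
    motif_offset: int | None = None
    evidence: list = field(default_factory=list)  # (label, expected, observed, match)

    @property
    def strict_motif(self) -> bool:
        return self.motif_observed != "" and all(
            m == "exact" for (lbl, e, o, m) in self.evidence if lbl and _is_motif_label(lbl)
        )


def _is_motif_label(label: str) -> bool:
    return label[0] in "DGGTR" and label[1:].isdigit() and 127 <= int(label[1:]) <= 131


def _match_class(observed: str, pos: PanelPosition) -> str:
    if observed == pos.expected:
        return "exact"
    if observed in pos.allowed:
        return "similar"
    return "mismatch"


def locate_pi_motif(
    sequence: str, panel: ResiduePanel | None = None
) -> tuple[int, str] | None:
    """Best DGGTR-like window in an unaligned sequence.

    Exact matches win; otherwise the window with the most class-compatible
    positions (exact counted above similar, leftmost breaks ties).  Windows
    with fewer than 3 of 5 compatible positions are rejected, returning
    None.  Returns (0-based offset, observed pentapeptide).
    """
    panel = panel or default_panel()
    motif_positions = sorted(panel.motif_positions, key=lambda p: p.offset)
    m = len(motif_positions)
    best: tuple[int, int, int] | None = None  # (compatible, exact, -offset)
    best_hit: tuple[int, str] | None = None
    for off in range(len(sequence) - m + 1):
        window = sequence[off : off + m]
        classes = [_match_class(window[i], motif_positions[i]) for i in range(m)]
        exact = sum(c == "exact" for c in classes)
        compatible = exact + sum(c == "similar" for c in classes)
        if compatible < 3:
            continue
        score = (compatible, exact, -off)
        if best is None or score > best:
            best = score
            best_hit = (off, window)
    return best_hit


def _evaluate_positions(
    residues: Mapping[str, str], panel: ResiduePanel
) -> tuple[str, list]:
    """Verdict and evidence from a {label: observed residue} mapping."""
    evidence = []
    verdict = "active"
    for pos in panel.positions:
        observed = residues.get(pos.label, "")
        if not observed or observed in GAP_CHARS:
            match = "absent"
        else:
            match = _match_class(observed, pos)
        evidence.append((pos.label, pos.expected, observed, match))
        if not pos.critical:
            continue
        if match in ("mismatch", "absent"):
            verdict = "inactive"
        elif match == "similar" and verdict == "active":
            verdict = "partial"
    return verdict, evidence


def classify_activity(
    sequence: str, panel: ResiduePanel | None = None, species_id: str = ""
) -> ActivityCall:
    """Activity verdict for one unaligned orthologue sequence.

    The Pi motif is located by scanning; the remaining panel positions are
    read at their offsets from the motif start (indels between the motif
    and the catalytic aspartate are not modelled here - use
    :func:`classify_alignment` with a real alignment when available).
    """
    panel = panel or default_panel()
    hit = locate_pi_motif(sequence, panel)
    if hit is None:
        return ActivityCall(
            species_id, "inactive",
            evidence=[(p.label, p.expected, "", "absent") for p in panel.positions],
        )
    off, motif_observed = hit
    residues = {}
    for pos in panel.positions:
        idx = off + pos.offset
        residues[pos.label] = sequence[idx] if 0 <= idx < len(sequence) else ""
    verdict, evidence = _evaluate_positions(residues, panel)
    return ActivityCall(species_id, verdict, motif_observed, off, evidence)


def classify_alignment(
    rows: Mapping[str, str],
    reference_id: str,
    panel: ResiduePanel | None = None,
) -> list[ActivityCall]:
    """Activity verdicts for every row of an alignment.

    Panel positions are defined on the Arabidopsis reference coordinates
    and transferred to the other rows through the alignment columns of the
    ``reference_id`` row (which must be the Arabidopsis-numbered sequence).
    """
    panel = panel or default_panel()
    if reference_id not in rows:
        raise KeyError(f"reference row {reference_id!r} not in alignment")
    ref_row = rows[reference_id]
    # Map 1-based ungapped reference positions to alignment columns.
    ref_columns: dict[int, int] = {}
    res_no = 0
    for col, ch in enumerate(ref_row):
        if ch not in GAP_CHARS:
            res_no += 1
            ref_columns[res_no] = col
    calls = []
    for sid, row in rows.items():
        residues = {}
        motif_chars = []
        for pos in panel.positions:
            ref_pos = pos.reference_position
            if ref_pos is None:
                ref_pos = panel.reference_motif_start + pos.offset
            col = ref_columns.get(ref_pos)
            observed = row[col] if col is not None and col < len(row) else ""
            residues[pos.label] = observed
            if 0 <= pos.offset < panel.motif_length:
                motif_chars.append(observed if observed else "-")
        verdict, evidence = _evaluate_positions(residues, panel)
        calls.append(
            ActivityCall(sid, verdict, "".join(motif_chars), None, evidence)
        )
    return calls


def column_information(
    column: Iterable[str],
    small_sample_correction: bool = False,
    alphabet_size: int = 20,
) -> float:
    """Information content of one alignment column, in bits.

    bits = log2(alphabet_size) - H with H the Shannon entropy of the
    observed amino-acid frequencies; gaps are excluded.  The optional
    WebLogo-style small-sample correction subtracts (s-1)/(2 ln2 n).
    """
    letters = [c for c in column if c not in GAP_CHARS]
    if not letters:
        return float("nan")
    values, counts = np.unique(np.array(letters), return_counts=True)
    p = counts / counts.sum()
    entropy = float(-(p * np.log2(p)).sum())
    bits = math.log2(alphabet_size) - entropy
    if small_sample_correction:
        bits -= (alphabet_size - 1) / (2 * math.log(2) * len(letters))
    return max(bits, 0.0)


def logo_matrix(
    rows: Sequence[str] | Mapping[str, str],
    small_sample_correction: bool = False,
) -> pd.DataFrame:
    """Per-column letter frequencies and information content of an
    alignment, one row per (column, residue).

    Columns with more than 50% gaps are flagged (``high_gap``).
    """
    if isinstance(rows, Mapping):
        rows = list(rows.values())
    if not rows:
        raise ValueError("empty alignment")
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ValueError("alignment rows have unequal lengths")
    records = []
    for col in range(ncol):
        letters = [r[col] for r in rows]
        gap_fraction = sum(c in GAP_CHARS for c in letters) / len(letters)
        observed = [c for c in letters if c not in GAP_CHARS]
        bits = column_information(letters, small_sample_correction)
        total = len(observed)
        freq = {c: observed.count(c) / total for c in sorted(set(observed))} if total else {}
        for residue, f in freq.items():
            records.append(
                {
                    "column": col + 1,
                    "residue": residue,
                    "frequency": f,
                    "bits": bits,
                    "high_gap": gap_fraction > 0.5,
                }
            )
    return pd.DataFrame(records, columns=["column", "residue", "frequency", "bits", "high_gap"])


def summarize_groups(groups: Mapping[str, Sequence[ActivityCall]]) -> pd.DataFrame:
    """Per-taxon tallies of strict motif conservation and verdicts."""
    rows = []
    for group, calls in groups.items():
        rows.append(
            {
                "group": group,
                "n_sequences": len(calls),
                "n_strict_motif": sum(c.strict_motif for c in calls),
                "n_active": sum(c.verdict == "active" for c in calls),
                "n_partial": sum(c.verdict == "partial" for c in calls),
                "n_inactive": sum(c.verdict == "inactive" for c in calls),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["group", "n_sequences", "n_strict_motif", "n_active", "n_partial", "n_inactive"],
    )


def synthetic_orthologue_set(
    n_total: int = 107,
    n_partial_variant: int = 1,
    n_inactive: int = 0,
    seed: int = 0,
    length: int = 220,
    divergence: float = 0.05,
) -> dict[str, str]:
    """SYNTHETIC orthologue cohort for exercising the classifier.

    Builds an Arabidopsis-like scaffold carrying DGGTR(127-131), S132 and
    D174, then emits ``n_total`` sequences: the bulk with the strict motif,
    ``n_partial_variant`` with the DGGVK substitution (conservative,
    partial verdict) and ``n_inactive`` with the GGTYAA-mimicking
    R131Y/S132A/D174A substitutions.  Background positions outside the
    panel diverge at the given per-residue rate.  These are synthetic
    stand-ins, not the real sequence sets.
    """
    panel = default_panel()
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    motif_start0 = panel.reference_motif_start - 1  # 0-based 126
    protected = {motif_start0 + p.offset for p in panel.positions}
    # resample until the scaffold carries no competing DGGTR-like window
    for _ in range(100):
        scaffold = list(rng.choice(aa, size=length))
        for pos in panel.positions:
            scaffold[motif_start0 + pos.offset] = pos.expected
        hit = locate_pi_motif("".join(scaffold), panel)
        if hit is not None and hit[0] == motif_start0:
            break
    else:
        raise RuntimeError("could not build a clean scaffold")

    def diverge(base: list[str]) -> list[str]:
        out = list(base)
        for i in range(length):
            if i in protected:
                continue
            if rng.random() < divergence:
                out[i] = str(rng.choice(aa))
        return out

    cohort: dict[str, str] = {}
    kinds = (
        ["strict"] * (n_total - n_partial_variant - n_inactive)
        + ["partial"] * n_partial_variant
        + ["inactive"] * n_inactive
    )
    for i, kind in enumerate(kinds):
        seq = diverge(scaffold)
        if kind == "partial":
            seq[motif_start0 + 3] = "V"  # T130V
            seq[motif_start0 + 4] = "K"  # R131K -> DGGVK
        elif kind == "inactive":
            seq[motif_start0 + 4] = "Y"  # R131Y
            seq[motif_start0 + 5] = "A"  # S132A
            seq[motif_start0 + 47] = "A"  # D174A
        cohort[f"synthetic_{kind}_{i:03d}"] = "".join(seq)
    return cohort
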