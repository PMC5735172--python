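"""Aggregation of 3'-end calls into analysis products.

Products mirror the downstream analyses of a 3'RACE-seq experiment:
per-position 3'-end density profiles, the split between unmodified and
tailed (modified) intermediates, tailing proportions, tail length box
statistics, tail nucleotide composition, and detection of the major
intermediates as profile peaks (named ``P<position>``).

Densities are normalized by the total number of retained calls for the
library/target, not by the counts inside the plotted range, so reads with
ends outside the range still contribute to the denominator.  Profiles are
computed per replicate library; only tail-length box statistics pool
replicates, and that pooling is explicit in the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "EndProfile",
    "TailingSummary",
    "BoxStats",
    "Peak",
    "build_profile",
    "split_modified",
    "tailing_fractions",
    "tail_composition",
    "tail_length_boxstats",
    "detect_peaks",
]

RETAINED = ("unmodified", "modified")


@dataclass
class EndProfile:
    target: str
    positions: np.ndarray  # reported coordinates, ascending
    counts: np.ndarray
    density: np.ndarray
    n_retained: int  # normalization denominator (all retained calls)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "count": self.counts,
                "density": self.density,
            }
        )


@dataclass
class TailingSummary:
    fraction_ge1: float  # proportion of retained reads with 1-30 nt tails
    fraction_ge2: float  # proportion with 2-30 nt tails
    tail_length_counts: dict[int, int] = field(default_factory=dict)
    n_retained: int = 0


@dataclass
class BoxStats:
    median: float
    q1: float
    q3: float
    iqr: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray
    n: int


@dataclass(frozen=True)
class Peak:
    position: int
    label: str
    height: float


def _retained(calls: pd.DataFrame, target: str | None = None) -> pd.DataFrame:
    sub = calls[calls["status"].isin(RETAINED)]
    if target is not None:
        sub = sub[sub["target"] == target]
    return sub


def build_profile(
    calls: pd.DataFrame,
    target: str | None = None,
    pos_range: tuple[int, int] | None = None,
) -> EndProfile:
    """Histogram of reported 3'-end positions over ``pos_range``.

    With no range, the profile spans the observed coordinate domain.
    Density = count / total retained calls for the target, so the profile
    sums to 1 over the full domain and to <= 1 over a sub-range.
    """
    sub = _retained(calls, target)
    ends = sub["end_reported"].astype(int) if len(sub) else pd.Series([], dtype=int)
    if pos_range is None:
        if len(ends):
            pos_range = (int(ends.min()), int(ends.max()))
        else:
            pos_range = (1, 1)
    lo, hi = pos_range
    positions = np.arange(lo, hi + 1)
    counts = (
        ends[(ends >= lo) & (ends <= hi)]
        .value_counts()
        .reindex(positions, fill_value=0)
        .to_numpy()
    )
    n_retained = int(len(sub))
    density = counts / n_retained if n_retained else np.zeros_like(counts, dtype=float)
    return EndProfile(
        target=target or "", positions=positions, counts=counts,
        density=density.astype(float), n_retained=n_retained,
    )


def split_modified(
    calls: pd.DataFrame,
    target: str | None = None,
    pos_range: tuple[int, int] | None = None,
) -> tuple[EndProfile, EndProfile]:
    """Partition the profile into unmodified and modified intermediates.

    Both profiles share the joint denominator, so their counts (and
    densities) sum position-wise to the joint profile.
    """
    joint = build_profile(calls, target, pos_range)
    rng = (int(joint.positions[0]), int(joint.positions[-1]))
    sub = _retained(calls, target)
    out = []
    for status in ("unmodified", "modified"):
        part = build_profile(
            sub[sub["status"] == status].assign(status=status), target=None, pos_range=rng
        )
        part.target = joint.target
        part.n_retained = joint.n_retained
        part.density = (
            part.counts / joint.n_retained
            if joint.n_retained
            else np.zeros_like(part.counts, dtype=float)
        )
        out.append(part)
    return out[0], out[1]


def tailing_fractions(calls: pd.DataFrame) -> TailingSummary:
    """Proportion of retained reads carrying non-templated tails."""
    sub = _retained(calls)
    n = int(len(sub))
    if n == 0:
        return TailingSummary(0.0, 0.0, {}, 0)
    lengths = sub.loc[sub["status"] == "modified", "tail_len"].astype(int)
    counts = lengths.value_counts().sort_index().to_dict()
    ge1 = int((lengths >= 1).sum())
    ge2 = int((lengths >= 2).sum())
    return TailingSummary(ge1 / n, ge2 / n, counts, n)


def tail_composition(
    calls: pd.DataFrame, min_len: int = 2, max_len: int = 30
) -> dict[str, float] | None:
    """Per-base fractions over all tail nucleotides in a length class.

    None when the length class is empty (composition undefined).
    """
    sub = calls[
        (calls["status"] == "modified")
        & (calls["tail_len"] >= min_len)
        & (calls["tail_len"] <= max_len)
    ]
    if len(sub) == 0:
        return None
    pooled = "".join(sub["tail_seq"])
    total = len(pooled)
    return {b: pooled.count(b) / total for b in "ACGT"}


def tail_length_boxstats(lengths) -> BoxStats:
    """Tukey box statistics of tail lengths.

    Quartiles use linear interpolation between order statistics; whiskers
    extend to the most extreme data within 1.5 x IQR of the box; points
    beyond are outliers.  Replicate pooling, when wanted, is done by the
    caller by concatenating replicate length vectors.
    """
    data = np.asarray(list(lengths), dtype=float)
    if data.size == 0:
        raise ValueError("no tail lengths")
    q1, med, q3 = np.percentile(data, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = data[(data >= lo_fence) & (data <= hi_fence)]
    return BoxStats(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=np.sort(data[(data < lo_fence) | (data > hi_fence)]),
        n=int(data.size),
    )


def detect_peaks(
    profile: EndProfile, min_density: float = 0.02, min_separation: int = 2
) -> list[Peak]:
    """Local density maxima of at least ``min_density``, separated by at
    least ``min_separation`` positions, labelled ``P<position>``.

    The defaults separate intermediates 7 nt apart while suppressing shot
    noise.  Boundary positions are eligible.
    """
    if len(profile.density) == 0:
        return []
    padded = np.concatenate([[-1.0], profile.density, [-1.0]])
    idx, props = find_peaks(padded, height=min_density, distance=max(min_separation, 1))
    peaks = [
        Peak(
            position=int(profile.positions[i - 1]),
            label=f"P{int(profile.positions[i - 1])}",
            height=float(padded[i]),
        )
        for i in idx
    ]
    return sorted(peaks, key=lambda p: p.position)
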