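"""Feature-anchored window extraction and profile averaging.

All instances of a protein feature are aligned on the first nucleotide
(or codon) coding their first residue; fixed windows of track values are
stacked into a matrix and averaged per relative position, the metagene
machinery behind feature-anchored profile plots.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyMatrixError
from .types import Dataset


@dataclass(frozen=True)
class WindowSpec:
    """Window of relative positions -upstream..+downstream around the anchor.

    ``unit`` is 'nucleotide' (windows over per-nt tracks) or 'codon'
    (windows over per-residue tracks such as tRNA concentration).
    """

    upstream: int = 50
    downstream: int = 100
    unit: str = "nucleotide"

    def __post_init__(self):
        if self.upstream < 0 or self.downstream < 0:
            raise ValueError("window extents must be non-negative")
        if self.upstream + self.downstream + 1 < 2:
            raise ValueError("window must cover at least 2 positions")
        if self.unit not in ("nucleotide", "codon"):
            raise ValueError(f"unknown window unit {self.unit!r}")

    @property
    def length(self) -> int:
        return self.upstream + self.downstream + 1

    @property
    def positions(self) -> np.ndarray:
        return np.arange(-self.upstream, self.downstream + 1)


#: window used for the visualization profiles (150 nt around the anchor,
#: predominantly downstream of it)
VISUALIZATION_WINDOW = WindowSpec(upstream=50, downstream=100)
#: window used for the correlation statistic (-50..+50 nt)
STATISTIC_WINDOW = WindowSpec(upstream=50, downstream=50)
#: codon-unit window covering the same mRNA region as the nucleotide one
CODON_WINDOW = WindowSpec(upstream=16, downstream=33, unit="codon")


def anchor_nucleotide(start_res: int) -> int:
    """0-based CDS index of the first nucleotide coding a 1-based residue."""
    if start_res < 1:
        raise ValueError("start_res must be >= 1")
    return 3 * (start_res - 1)


def extract_window(values: np.ndarray, anchor: int, spec: WindowSpec) -> np.ndarray:
    """Copy ``values[anchor-upstream .. anchor+downstream]``, NaN outside.

    Output length is always ``spec.length`` regardless of edge effects;
    the anchor itself must lie inside the track.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if not 0 <= anchor < n:
        raise IndexError(f"anchor {anchor} outside track of length {n}")
    out = np.full(spec.length, np.nan)
    lo = anchor - spec.upstream
    hi = anchor + spec.downstream + 1
    src_lo, src_hi = max(lo, 0), min(hi, n)
    out[src_lo - lo:src_hi - lo] = values[src_lo:src_hi]
    return out


@dataclass
class ProfileMatrix:
    """Stacked feature-anchored windows: one row per feature instance."""

    data: np.ndarray
    row_ids: list[tuple[str, int]]
    spec: WindowSpec
    feature_name: str = ""
    track_name: str = ""

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def positions(self) -> np.ndarray:
        return self.spec.positions

    def complete_rows(self) -> np.ndarray:
        """Rows without any missing value (required by the correlation test)."""
        return self.data[np.all(np.isfinite(self.data), axis=1)]


@dataclass
class AverageProfile:
    """Per-position mean of available values with contributing counts."""

    positions: np.ndarray
    mean: np.ndarray
    count: np.ndarray
    smoothed: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({
            "relative_position": self.positions,
            "mean": self.mean,
            "count": self.count,
        })
        if self.smoothed is not None:
            frame["smoothed_mean"] = self.smoothed
        return frame


def build_profile_matrix(dataset: Dataset, feature_name: str, track_name: str,
                         spec: WindowSpec = STATISTIC_WINDOW) -> ProfileMatrix:
    """One window row per feature instance on a retained transcript.

    Instances whose protein was dropped upstream contribute no row.  For
    codon-unit windows the anchor is the feature's first residue and the
    track is looked up among per-codon tracks.  Rows are ordered by
    (protein_id, start_res).
    """
    rows: list[np.ndarray] = []
    row_ids: list[tuple[str, int]] = []
    for inst in dataset.instances_of(feature_name):
        record = dataset.transcripts.get(inst.protein_id)
        if record is None:
            continue
        if spec.unit == "codon":
            values = record.codon_tracks.get(track_name)
            anchor = inst.start_res - 1
        else:
            values = record.tracks.get(track_name)
            anchor = record.utr5_len + anchor_nucleotide(inst.start_res)
        if values is None or not 0 <= anchor < len(values):
            continue
        rows.append(extract_window(values, anchor, spec))
        row_ids.append((inst.protein_id, inst.start_res))
    if not rows:
        raise EmptyMatrixError(feature_name)
    return ProfileMatrix(np.vstack(rows), row_ids, spec, feature_name, track_name)


def average_profile(matrix: ProfileMatrix) -> AverageProfile:
    """Missing-aware per-position arithmetic mean over the matrix rows."""
    if matrix.n_rows == 0:
        raise EmptyMatrixError(matrix.feature_name)
    finite = np.isfinite(matrix.data)
    count = finite.sum(axis=0)
    total = np.where(finite, matrix.data, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return AverageProfile(
        positions=matrix.positions.copy(), mean=mean, count=count,
        meta={"feature": matrix.feature_name, "track": matrix.track_name,
              "unit": matrix.spec.unit, "n_rows": matrix.n_rows},
    )


def smooth(values: np.ndarray, w: int) -> np.ndarray:
    """Centered moving average with window ``w``, missing-aware.

    Position i averages the finite values in
    ``[i - floor((w-1)/2), i + ceil((w-1)/2)]`` intersected with the
    valid range, so edges shrink rather than pad; an even ``w`` takes one
    extra position on the right.  ``w = 1`` is the identity.
    """
    if w < 1:
        raise ValueError("window size must be >= 1")
    values = np.asarray(values, dtype=float)
    n = len(values)
    left = (w - 1) // 2
    right = w - 1 - left
    out = np.full(n, np.nan)
    for i in range(n):
        seg = values[max(0, i - left):min(n, i + right + 1)]
        seg = seg[np.isfinite(seg)]
        if seg.size:
            out[i] = seg.mean()
    return out
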