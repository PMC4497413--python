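"""Track conditioning: outlier exclusion, per-base z-scoring, UTR trimming,
translation-discrepancy screening, and codon-level tRNA tracks.

Conventions fixed here so every downstream number is reproducible:

* outlier and z-score statistics are pooled over the whole dataset (one
  global filter, not per transcript);
* all standard deviations are population (ddof=0) standard deviations;
* the outlier boundary uses a strict ``>``: a value exactly at
  mean + k*sd is kept.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateBaseError, InsufficientDataError, TrnaLookupError
from .simulate import translate_cds
from .types import Dataset, TranscriptRecord


@dataclass(frozen=True)
class OutlierPolicy:
    """Exclude values more than ``k`` pooled standard deviations above the
    pooled mean (default k = 1.5)."""

    k: float = 1.5

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("k must be positive")


@dataclass
class BaseStats:
    """Pooled per-base mean/sd/count of a raw track over coding positions."""

    mu: dict[str, float] = field(default_factory=dict)
    sigma: dict[str, float] = field(default_factory=dict)
    n: dict[str, int] = field(default_factory=dict)


def outlier_threshold(values: np.ndarray, k: float) -> tuple[float, float, float]:
    """(mean, population sd, threshold) over the finite entries of ``values``."""
    finite = values[np.isfinite(values)]
    if finite.size < 2:
        raise InsufficientDataError("need at least 2 finite values for outlier stats")
    mean = float(finite.mean())
    sd = float(finite.std(ddof=0))
    return mean, sd, mean + k * sd


def remove_outliers(dataset: Dataset, track_name: str,
                    policy: OutlierPolicy = OutlierPolicy()) -> int:
    """Set to missing every track value above mean + k*sd and return the count.

    Mean and sd are computed once over all finite values of the track in
    the whole dataset.  Modifies track arrays in place.
    """
    chunks = [r.tracks[track_name] for r in dataset.transcripts.values()
              if track_name in r.tracks]
    pooled = np.concatenate(chunks) if chunks else np.empty(0)
    _, _, threshold = outlier_threshold(pooled, policy.k)
    removed = 0
    for record in dataset.transcripts.values():
        values = record.tracks.get(track_name)
        if values is None:
            continue
        mask = values > threshold  # NaN-safe: NaN compares False
        removed += int(mask.sum())
        values[mask] = np.nan
    return removed


def zscore_by_base(dataset: Dataset, track_name: str) -> BaseStats:
    """Normalize a track to per-nucleotide-identity z-scores, in place.

    The raw score ranges of the four bases differ (paired propensity is
    base dependent), which would bias feature profiles through amino-acid
    composition; z-scoring each base class to mean 0 / sd 1 removes that
    bias.  Statistics are pooled genome-wide over coding positions.
    Missing values stay missing.  Raises :class:`DegenerateBaseError` if a
    base class has zero variance.
    """
    per_base_values: dict[str, list[np.ndarray]] = {b: [] for b in "ACGT"}
    for record in dataset.transcripts.values():
        values = record.tracks.get(track_name)
        if values is None:
            continue
        bases = np.frombuffer(record.cds.encode(), dtype="S1").astype("U1")
        for b in "ACGT":
            sel = values[bases == b]
            per_base_values[b].append(sel[np.isfinite(sel)])

    stats = BaseStats()
    for b in "ACGT":
        pooled = (np.concatenate(per_base_values[b]) if per_base_values[b]
                  else np.empty(0))
        if pooled.size == 0:
            continue  # base absent from the dataset: nothing to normalize
        if pooled.size < 2:
            raise InsufficientDataError(f"base {b}: fewer than 2 finite values")
        mu, sigma = float(pooled.mean()), float(pooled.std(ddof=0))
        if sigma == 0.0:
            raise DegenerateBaseError(b)
        stats.mu[b], stats.sigma[b], stats.n[b] = mu, sigma, int(pooled.size)

    for record in dataset.transcripts.values():
        values = record.tracks.get(track_name)
        if values is None:
            continue
        bases = np.frombuffer(record.cds.encode(), dtype="S1").astype("U1")
        for b in stats.mu:
            sel = bases == b
            values[sel] = (values[sel] - stats.mu[b]) / stats.sigma[b]
    return stats


def trim_utrs(record: TranscriptRecord) -> TranscriptRecord:
    """Return a copy restricted to the CDS (5'/3' UTR track values removed)."""
    u5, u3 = record.utr5_len, record.utr3_len
    if u5 == 0 and u3 == 0:
        return record.copy()
    out = record.copy()
    trimmed: dict[str, np.ndarray] = {}
    for name, values in record.tracks.items():
        if u5 + u3 >= len(values):
            raise ValueError(f"UTRs cover the whole track {name!r}")
        kept = values[u5:len(values) - u3]
        if len(kept) % 3 != 0:
            raise ValueError(
                f"track {name!r}: trimmed length {len(kept)} is not a multiple of 3"
            )
        trimmed[name] = kept.copy()
    out.tracks = trimmed
    out.utr5_len = out.utr3_len = 0
    problems = out.validate()
    if problems:
        raise ValueError("; ".join(problems))
    return out


def pad_utrs(record: TranscriptRecord, utr5_len: int, utr3_len: int,
             rng: np.random.Generator | None = None) -> TranscriptRecord:
    """Inverse of :func:`trim_utrs` for synthetic records: prepend/append
    UTR track values (random if ``rng`` given, else zeros)."""
    if record.utr5_len or record.utr3_len:
        raise ValueError("record already has UTRs")
    out = record.copy()
    for name, values in record.tracks.items():
        left = rng.normal(size=utr5_len) if rng is not None else np.zeros(utr5_len)
        right = rng.normal(size=utr3_len) if rng is not None else np.zeros(utr3_len)
        out.tracks[name] = np.concatenate([left, values, right])
    out.utr5_len, out.utr3_len = utr5_len, utr3_len
    return out


def translation_discrepancy(cds: str, protein: str) -> float:
    """Fraction of positional mismatches between translate(CDS) and protein.

    Positional comparison without indel alignment; a length difference
    counts every unmatched residue as a mismatch; an internal stop codon
    translates to '*' and mismatches from that point on.  Records above a
    5% discrepancy are excluded by the pipeline (strictly greater:
    exactly 5% is retained).
    """
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    translated = translate_cds(cds)
    denom = max(len(translated), len(protein))
    if denom == 0:
        return 0.0
    paired = min(len(translated), len(protein))
    mismatches = sum(a != b for a, b in zip(translated[:paired], protein[:paired]))
    mismatches += denom - paired
    return mismatches / denom


def filter_discrepant(dataset: Dataset, max_fraction: float = 0.05) -> int:
    """Drop records whose translation discrepancy exceeds ``max_fraction``.

    Returns the number of dropped records; their feature rows are dropped
    with them.
    """
    bad = [tid for tid, r in dataset.transcripts.items()
           if translation_discrepancy(r.cds, r.protein) > max_fraction]
    for tid in bad:
        del dataset.transcripts[tid]
    if bad:
        bad_set = set(bad)
        dataset.features = [f for f in dataset.features if f.protein_id not in bad_set]
    return len(bad)


def build_codon_track(record: TranscriptRecord, trna_table,
                      name: str = "trna") -> np.ndarray:
    """Per-residue vector of relative tRNA concentrations (stop excluded).

    Stored under ``record.codon_tracks[name]``; length equals the protein
    length.  Raises :class:`TrnaLookupError` naming transcript, position
    and codon when a codon is absent from the table.
    """
    n_res = len(record.protein)
    values = np.empty(n_res)
    for i in range(n_res):
        codon = record.cds[3 * i:3 * i + 3]
        try:
            values[i] = trna_table[codon]
        except TrnaLookupError:
            raise TrnaLookupError(
                f"transcript {record.transcript_id}, codon index {i}: "
                f"codon {codon} absent from tRNA table"
            ) from None
    record.codon_tracks[name] = values
    return values
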