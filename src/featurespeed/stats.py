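"""The correlation-distribution association test and related statistics.

If a protein feature shapes a local mRNA property, the windows around its
instances look alike: their pairwise Pearson correlations shift to
positive values, while correlations among random same-length mRNA
segments centre on zero.  The association test compares the two
distributions with a one-sided unpaired t-test (H1: observed mean is
larger).  Also here: cross-correlation between two average profiles to
quantify similarity and displacement (lag), and the positively charged
residue enrichment control.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import DegeneratePairError, InsufficientDataError
from .profiles import ProfileMatrix
from .types import Dataset

POSITIVE_RESIDUES = frozenset("KR")


def pearson(x, y) -> float:
    """Pearson product-moment correlation of two complete vectors.

    Requires equal length >= 3, finite entries, and nonzero variance in
    both vectors; otherwise the pair is degenerate and the caller should
    count and skip it.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length 1-D vectors of length >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("missing values not allowed in correlation vectors")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        raise DegeneratePairError("zero variance in one of the vectors")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


@dataclass
class CorrelationDistribution:
    """All pairwise Pearson correlations among a set of complete windows."""

    values: np.ndarray
    n_windows: int
    n_pairs: int
    n_degenerate_dropped: int
    seed: int | None = None

    def mean(self) -> float:
        return float(self.values.mean())


def _pairwise_correlations(windows: np.ndarray) -> tuple[np.ndarray, int]:
    """Upper-triangle pairwise correlations; degenerate pairs dropped.

    A pair is degenerate when either vector is constant.  Returns
    (values, n_degenerate_dropped).
    """
    n = windows.shape[0]
    constant = windows.std(axis=1) == 0
    usable = windows[~constant]
    m = usable.shape[0]
    n_degenerate = n * (n - 1) // 2 - m * (m - 1) // 2
    if m < 2:
        return np.empty(0), n_degenerate
    corr = np.corrcoef(usable)
    iu = np.triu_indices(m, k=1)
    return np.clip(corr[iu], -1.0, 1.0), n_degenerate


def observed_distribution(matrix: ProfileMatrix, max_windows: int = 1000,
                          seed: int | None = None) -> CorrelationDistribution:
    """Pairwise correlations among the complete feature-anchored windows.

    Only windows without missing values enter (Pearson needs complete
    vectors).  If more than ``max_windows`` are available they are
    subsampled without replacement (seeded) to keep the pair count
    desk-scale and comparable with the background's.
    """
    windows = matrix.complete_rows()
    if windows.shape[0] < 2:
        raise InsufficientDataError(
            f"{matrix.feature_name!r}/{matrix.track_name!r}: "
            f"{windows.shape[0]} complete windows, need >= 2"
        )
    if windows.shape[0] > max_windows:
        rng = np.random.default_rng(seed)
        keep = rng.choice(windows.shape[0], size=max_windows, replace=False)
        windows = windows[np.sort(keep)]
    values, n_degenerate = _pairwise_correlations(windows)
    return CorrelationDistribution(
        values=values, n_windows=windows.shape[0], n_pairs=len(values),
        n_degenerate_dropped=n_degenerate, seed=seed,
    )


def eligible_starts(dataset: Dataset, track_name: str,
                    window_len: int) -> list[tuple[str, int]]:
    """All (transcript_id, offset) pairs yielding a complete segment."""
    out: list[tuple[str, int]] = []
    for tid in sorted(dataset.transcripts):
        values = dataset.transcripts[tid].tracks.get(track_name)
        if values is None or len(values) < window_len:
            continue
        finite = np.isfinite(values).astype(int)
        run = np.convolve(finite, np.ones(window_len, dtype=int), mode="valid")
        for off in np.nonzero(run == window_len)[0]:
            out.append((tid, int(off)))
    return out


def background_distribution(dataset: Dataset, track_name: str, window_len: int,
                            n_vectors: int = 1000,
                            seed: int | None = None) -> CorrelationDistribution:
    """Correlations among random same-length segments from the mRNA pool.

    Start positions are uniform over all eligible (transcript, offset)
    pairs — long transcripts are proportionally more likely — drawn with
    replacement across the ``n_vectors`` draws.  This is the null the
    observed distribution is tested against.
    """
    pool = eligible_starts(dataset, track_name, window_len)
    if not pool:
        raise InsufficientDataError(
            f"track {track_name!r}: no complete {window_len}-mer segment exists"
        )
    rng = np.random.default_rng(seed)
    picks = rng.integers(len(pool), size=n_vectors)
    segments = np.vstack([
        dataset.transcripts[pool[i][0]].tracks[track_name][pool[i][1]:pool[i][1] + window_len]
        for i in picks
    ])
    values, n_degenerate = _pairwise_correlations(segments)
    return CorrelationDistribution(
        values=values, n_windows=n_vectors, n_pairs=len(values),
        n_degenerate_dropped=n_degenerate, seed=seed,
    )


@dataclass
class CorrelationTestResult:
    feature_name: str
    track_name: str
    mean_obs: float
    mean_bg: float
    t_statistic: float
    p_value: float
    n_instances: int = 0
    n_obs_windows: int = 0
    n_bg_windows: int = 0


def association_test(obs: CorrelationDistribution, bg: CorrelationDistribution,
                     feature_name: str = "", track_name: str = "",
                     n_instances: int = 0,
                     equal_var: bool = False) -> CorrelationTestResult:
    """One-sided unpaired t-test: is the observed mean correlation larger?

    Welch (unequal-variance) form by default; ``equal_var=True`` gives
    the pooled-variance Student form.
    """
    if len(obs.values) < 2 or len(bg.values) < 2:
        raise InsufficientDataError("both correlation distributions need >= 2 values")
    if np.array_equal(obs.values, bg.values):
        t_stat, p = 0.0, 0.5  # identical samples: exactly the symmetric null
    else:
        t_stat, p = sps.ttest_ind(obs.values, bg.values, equal_var=equal_var,
                                  alternative="greater")
    return CorrelationTestResult(
        feature_name=feature_name, track_name=track_name,
        mean_obs=obs.mean(), mean_bg=bg.mean(),
        t_statistic=float(t_stat), p_value=float(p),
        n_instances=n_instances, n_obs_windows=obs.n_windows,
        n_bg_windows=bg.n_windows,
    )


@dataclass
class CrossCorrelationResult:
    """Pearson correlation between two average profiles at each lag."""

    lags: np.ndarray
    r: np.ndarray
    best_lag: int
    r_at_best: float


def cross_correlation(profile_a: np.ndarray, profile_b: np.ndarray,
                      max_lag: int) -> CrossCorrelationResult:
    """Scan lags -L..+L; positive lag means B is displaced downstream of A.

    At lag k the overlap pairs ``a[i]`` with ``b[i + k]``.  The best lag
    maximizes r, ties broken toward smaller |lag| and then toward the
    negative lag.  Every lag must leave an overlap of >= 3 finite pairs.
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("profiles must share one common axis")
    n = len(a)
    if n - max_lag < 3:
        raise InsufficientDataError(
            f"overlap {n - max_lag} < 3 at lag {max_lag}"
        )
    lags = np.arange(-max_lag, max_lag + 1)
    r = np.full(len(lags), np.nan)
    for j, lag in enumerate(lags):
        if lag >= 0:
            xa, xb = a[:n - lag], b[lag:]
        else:
            xa, xb = a[-lag:], b[:n + lag]
        keep = np.isfinite(xa) & np.isfinite(xb)
        if keep.sum() < 3:
            raise InsufficientDataError(f"overlap too short at lag {lag}")
        try:
            r[j] = pearson(xa[keep], xb[keep])
        except DegeneratePairError:
            r[j] = np.nan
    finite = np.isfinite(r)
    if not finite.any():
        raise DegeneratePairError("profiles degenerate at every lag")
    order = sorted(
        (j for j in range(len(lags)) if finite[j]),
        key=lambda j: (-r[j], abs(int(lags[j])), int(lags[j])),
    )
    best = order[0]
    return CrossCorrelationResult(lags=lags, r=r, best_lag=int(lags[best]),
                                  r_at_best=float(r[best]))


@dataclass
class EnrichmentResult:
    feature_name: str
    window_fraction: float
    proteome_fraction: float
    ratio: float
    p_value: float
    n_window_residues: int
    n_window_positive: int


def positive_residue_enrichment(dataset: Dataset, feature_name: str,
                                window_res: tuple[int, int] = (16, 33)
                                ) -> EnrichmentResult:
    """Enrichment of positively charged residues (K, R) around a feature.

    Positive charge slows elongation on its own, so a feature whose
    windows are K/R-enriched could show an occupancy pattern for that
    reason alone; this control compares the K/R proportion in the
    -upstream..+downstream residue windows around the feature anchors
    with the proteome-wide proportion (exact binomial test, two-sided).
    """
    up, down = window_res
    proteome_n = proteome_k = 0
    for record in dataset.transcripts.values():
        proteome_n += len(record.protein)
        proteome_k += sum(c in POSITIVE_RESIDUES for c in record.protein)
    if proteome_k == 0 or proteome_n == 0:
        raise ValueError("no positively charged residues in the proteome")
    p0 = proteome_k / proteome_n

    win_n = win_k = 0
    for inst in dataset.instances_of(feature_name):
        record = dataset.transcripts.get(inst.protein_id)
        if record is None:
            continue
        centre = inst.start_res - 1
        lo = max(0, centre - up)
        hi = min(len(record.protein), centre + down + 1)
        segment = record.protein[lo:hi]
        win_n += len(segment)
        win_k += sum(c in POSITIVE_RESIDUES for c in segment)
    if win_n == 0:
        raise InsufficientDataError(f"no residues in windows of {feature_name!r}")
    p_value = sps.binomtest(win_k, win_n, p0, alternative="two-sided").pvalue
    return EnrichmentResult(
        feature_name=feature_name, window_fraction=win_k / win_n,
        proteome_fraction=p0, ratio=(win_k / win_n) / p0,
        p_value=float(p_value), n_window_residues=win_n, n_window_positive=win_k,
    )
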