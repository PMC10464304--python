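"""Genome-wide co-occurrence analyses on coverage tracks.

The workflow mirrors a standard double-mark ChIP/CIDOP comparison:

1. tile the genome into fixed-width bins (blacklist-aware) and attach
   per-bin mean signals for each track;
2. rank bins by a conditioning mark, split them into equal-count quantile
   groups, and compute the Pearson correlation of two other tracks within
   each group (decile-conditioned correlation);
3. fragment broad peaks into mononucleosome-scale windows, cluster the
   fragments by k-means on their per-track signals;
4. score interval overlaps against a shuffle null that conserves the
   interval-length multiset.

All coordinates are 0-based half-open; a shared boundary is never an
overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import IntervalSet
from .tracks import CoverageTrack

__all__ = [
    "GenomeBins",
    "DecileReport",
    "FragmentClusterReport",
    "EnrichmentReport",
    "bin_genome",
    "mean_signal",
    "binned_correlation",
    "quantile_split",
    "conditional_correlation",
    "fragment_peaks",
    "cluster_fragments",
    "shuffle_intervals",
    "state_enrichment",
    "peak_overlap_enrichment",
    "region_matrix",
]

SUMMARY_QUANTILES = (0.05, 0.25, 0.5, 0.75, 0.95)


@dataclass
class GenomeBins:
    """Fixed-width genome tiling with per-track mean-signal columns."""

    df: pd.DataFrame  # chrom, start, end + one column per track
    bin_size: int

    def __len__(self):
        return len(self.df)

    @property
    def track_columns(self) -> list[str]:
        return [c for c in self.df.columns if c not in ("chrom", "start", "end")]

    def add_track(self, name: str, track: CoverageTrack) -> "GenomeBins":
        self.df[name] = mean_signal(track, self)
        return self


def bin_genome(
    chrom_sizes: dict[str, int],
    bin_size: int,
    blacklist: IntervalSet | None = None,
) -> GenomeBins:
    """Tile every chromosome from 0 in ``bin_size`` steps.

    The trailing short bin is kept. Bins overlapping the blacklist by any
    amount are dropped entirely (not clipped) so remaining bin widths stay
    uniform.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    frames = []
    for chrom, length in chrom_sizes.items():
        starts = np.arange(0, length, bin_size, dtype=np.int64)
        ends = np.minimum(starts + bin_size, length)
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    df = pd.concat(frames, ignore_index=True)
    if blacklist is not None and len(blacklist):
        extra = set(blacklist.df["chrom"]) - set(chrom_sizes)
        if extra:
            warnings.warn(
                f"blacklist chromosomes absent from chrom.sizes ignored: {sorted(extra)}"
            )
        hit = blacklist.overlap_bp(
            df["chrom"].to_numpy(), df["start"].to_numpy(), df["end"].to_numpy()
        )
        df = df[hit == 0].reset_index(drop=True)
    return GenomeBins(df=df, bin_size=bin_size)


def mean_signal(track: CoverageTrack, intervals) -> np.ndarray:
    """Base-weighted mean of the track over each interval.

    ``intervals`` may be a GenomeBins or an IntervalSet; uncovered bases
    contribute zero, and intervals on chromosomes the track does not carry
    get mean 0 with a warning.
    """
    df = intervals.df
    missing = set(df["chrom"].unique()) - set(track.chrom_sizes)
    if missing:
        warnings.warn(f"intervals on chromosomes absent from track: {sorted(missing)}")
    return track.mean_over(
        df["chrom"].to_numpy(), df["start"].to_numpy(), df["end"].to_numpy()
    )


def binned_correlation(
    track_a: CoverageTrack,
    track_b: CoverageTrack,
    bin_size: int,
    blacklist: IntervalSet | None = None,
) -> float:
    """Pearson r between two tracks over per-bin means.

    Returns NaN (undefined) when either vector has zero variance.
    """
    bins = bin_genome(track_a.chrom_sizes, bin_size, blacklist)
    a = mean_signal(track_a, bins)
    b = mean_signal(track_b, bins)
    finite = np.isfinite(a) & np.isfinite(b)
    a, b = a[finite], b[finite]
    if len(a) < 3:
        raise ValueError("need >= 3 finite bins for a correlation")
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class DecileReport:
    """Quantile grouping of bins by one track, with per-group summaries."""

    bins: GenomeBins
    ranking_track: str
    k: int
    group: np.ndarray  # 1..k per bin, 1 = highest ranking signal

    def group_frames(self):
        for g in range(1, self.k + 1):
            yield g, self.bins.df[self.group == g]

    def summaries(self, track: str) -> pd.DataFrame:
        rows = []
        for g, sub in self.group_frames():
            q = sub[track].quantile(SUMMARY_QUANTILES)
            rows.append(
                {
                    "group": g,
                    "n": len(sub),
                    "p5": q[0.05],
                    "p25": q[0.25],
                    "median": q[0.5],
                    "p75": q[0.75],
                    "p95": q[0.95],
                    "mean": sub[track].mean(),
                }
            )
        return pd.DataFrame(rows)


def quantile_split(bins: GenomeBins, ranking_track: str, k: int = 10) -> DecileReport:
    """Rank bins by descending signal and split into k equal-count groups.

    Ties are broken by genomic order (chrom, start), so the split is
    deterministic. Group sizes differ by at most one, with the larger
    groups first; group 1 holds the highest-signal bins.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    n = len(bins)
    if n < k:
        raise ValueError("fewer bins than groups")
    if ranking_track not in bins.df.columns:
        raise KeyError(f"no track column {ranking_track!r}")
    # stable sort on genomic order first, then descending signal
    order = np.lexsort(
        (
            bins.df["start"].to_numpy(),
            bins.df["chrom"].to_numpy(),
            -bins.df[ranking_track].to_numpy(),
        )
    )
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    group_of_rank = np.repeat(np.arange(1, k + 1), sizes)
    group = np.empty(n, dtype=np.int64)
    group[order] = group_of_rank
    return DecileReport(bins=bins, ranking_track=ranking_track, k=k, group=group)


def conditional_correlation(
    report: DecileReport, track_x: str, track_y: str
) -> pd.DataFrame:
    """Pearson r(track_x, track_y) within each quantile group.

    Zero-variance groups are flagged undefined (NaN r).
    """
    rows = []
    for g, sub in report.group_frames():
        if len(sub) < 3:
            raise ValueError(f"group {g} has fewer than 3 bins")
        x = sub[track_x].to_numpy()
        y = sub[track_y].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            r = float("nan")
        else:
            r = float(np.corrcoef(x, y)[0, 1])
        rows.append({"group": g, "n": len(sub), "r": r})
    return pd.DataFrame(rows)


def fragment_peaks(
    peaks: IntervalSet,
    chrom_sizes: dict[str, int],
    fragment_size: int = 150,
    retention: float = 0.5,
) -> IntervalSet:
    """Tile the genome and keep fragments mostly inside the peak union.

    The genome is tiled from 0 in ``fragment_size`` steps; a fragment is
    kept iff its overlap with the merged peaks is >= retention * its own
    width (inclusive boundary, so a 150 bp fragment needs >= 75 bp at the
    default retention of 0.5).
    """
    if fragment_size <= 0:
        raise ValueError("fragment_size must be > 0")
    if not 0 < retention <= 1:
        raise ValueError("retention must be in (0, 1]")
    kept = []
    for chrom, length in chrom_sizes.items():
        starts = np.arange(0, length, fragment_size, dtype=np.int64)
        ends = np.minimum(starts + fragment_size, length)
        ov = peaks.overlap_bp(np.full(len(starts), chrom, dtype=object), starts, ends)
        need = retention * (ends - starts)
        sel = ov >= need
        kept.extend((chrom, int(s), int(e)) for s, e in zip(starts[sel], ends[sel]))
    out = IntervalSet.from_records(kept) if kept else IntervalSet.empty()
    out.role = "fragments"
    return out


@dataclass
class FragmentClusterReport:
    fragments: IntervalSet
    signal: pd.DataFrame  # per-fragment mean per track
    labels: np.ndarray  # cluster id per fragment, 0 = highest ordering-track mean
    ordering_track: str
    cluster_means: pd.DataFrame  # per-cluster mean per track, row per cluster


def cluster_fragments(
    fragments: IntervalSet,
    signal: pd.DataFrame,
    k: int,
    ordering_track: str,
    seed: int = 0,
    n_init: int = 10,
) -> FragmentClusterReport:
    """k-means on per-fragment signals, clusters ordered by signal strength.

    Columns are standardized to zero mean / unit variance before
    clustering (track scales differ by orders of magnitude); clusters are
    relabeled 0..k-1 in decreasing order of the ordering track's cluster
    mean so cluster 0 is always the strongest.
    """
    from sklearn.cluster import KMeans

    if k < 1:
        raise ValueError("k must be >= 1")
    X = signal.to_numpy(dtype=float)
    if len(X) < k:
        raise ValueError("fewer fragments than clusters")
    if len(np.unique(X, axis=0)) < k:
        raise ValueError("k exceeds the number of distinct signal rows")
    sd = X.std(axis=0)
    Z = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(Z)
    order_means = np.array(
        [signal[ordering_track].to_numpy()[raw == c].mean() for c in range(k)]
    )
    rank = np.argsort(-order_means)  # rank[i] = raw label of i-th strongest
    relabel = np.empty(k, dtype=np.int64)
    relabel[rank] = np.arange(k)
    labels = relabel[raw]
    cluster_means = pd.DataFrame(
        [signal[labels == c].mean() for c in range(k)],
    ).reset_index(drop=True)
    cluster_means.insert(0, "cluster", np.arange(k))
    cluster_means.insert(1, "n", [int(np.sum(labels == c)) for c in range(k)])
    return FragmentClusterReport(
        fragments=fragments,
        signal=signal,
        labels=labels,
        ordering_track=ordering_track,
        cluster_means=cluster_means,
    )


def shuffle_intervals(
    template: IntervalSet,
    chrom_sizes: dict[str, int],
    blacklist: IntervalSet | None = None,
    seed: int = 0,
    max_tries: int = 1000,
) -> IntervalSet:
    """Randomly re-place intervals, conserving the length multiset.

    Each interval keeps its length and lands uniformly on the genome
    (chromosome chosen proportional to admissible starts) avoiding any
    blacklist overlap; shuffled intervals may overlap each other, matching
    the behavior of the classic shuffle tool.
    """
    rng = np.random.default_rng(seed)
    chroms = list(chrom_sizes)
    placed = []
    for _, _, length in ((0, 0, int(l)) for l in template.lengths):
        starts_per_chrom = np.array(
            [max(0, chrom_sizes[c] - length + 1) for c in chroms], dtype=float
        )
        if starts_per_chrom.sum() == 0:
            raise ValueError(f"no chromosome can host an interval of length {length}")
        p = starts_per_chrom / starts_per_chrom.sum()
        for _try in range(max_tries):
            c = chroms[rng.choice(len(chroms), p=p)]
            s = int(rng.integers(0, chrom_sizes[c] - length + 1))
            if blacklist is None or not len(blacklist):
                placed.append((c, s, s + length))
                break
            if blacklist.overlap_bp([c], np.array([s]), np.array([s + length]))[0] == 0:
                placed.append((c, s, s + length))
                break
        else:
            raise ValueError(
                f"could not place an interval of length {length} off-blacklist "
                f"after {max_tries} tries"
            )
    out = IntervalSet.from_records(placed)
    out.role = "shuffled"
    return out


@dataclass
class EnrichmentReport:
    df: pd.DataFrame  # category, observed, expected, ratio, overlap_pct, p, n_null


def _empirical_p(observed: float, null: np.ndarray) -> float:
    """Add-one empirical p-value: P(null >= observed)."""
    return (1 + int(np.sum(null >= observed))) / (1 + len(null))


def state_enrichment(
    peaks: IntervalSet,
    states: IntervalSet,
    chrom_sizes: dict[str, int],
    blacklist: IntervalSet | None = None,
    n_shuffles: int = 10,
    seed: int = 0,
) -> EnrichmentReport:
    """Per-state overlap of chromatin-state regions with peaks vs shuffles.

    For each state label: observed = number of state regions overlapping
    at least one peak by >= 1 bp; expected = the mean of the same count
    against shuffled peak sets of equal number and length.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if "name" not in states.df.columns:
        raise ValueError("states must carry a label column")
    nulls = [
        shuffle_intervals(peaks, chrom_sizes, blacklist, seed=seed + i)
        for i in range(n_shuffles)
    ]
    rows = []
    for label, sub in states.df.groupby("name", sort=True):
        if len(sub) == 0:
            warnings.warn(f"state {label!r} has zero regions; omitted")
            continue
        regions = IntervalSet(sub[["chrom", "start", "end"]])
        observed = int(regions.overlaps_any(peaks).sum())
        null = np.array([int(regions.overlaps_any(nl).sum()) for nl in nulls])
        expected = float(null.mean())
        rows.append(
            {
                "category": label,
                "observed": observed,
                "expected": expected,
                "ratio": observed / expected if expected > 0 else float("inf") if observed else 0.0,
                "overlap_pct": 100.0 * observed / len(sub),
                "p": _empirical_p(observed, null),
                "n_null": n_shuffles,
            }
        )
    return EnrichmentReport(df=pd.DataFrame(rows))


def peak_overlap_enrichment(
    peaks_a: IntervalSet,
    peaks_b: IntervalSet,
    chrom_sizes: dict[str, int],
    blacklist: IntervalSet | None = None,
    n_permutations: int = 10,
    seed: int = 0,
) -> EnrichmentReport:
    """Overlap % of peaks A with peak set B, vs shuffled-A permutations."""
    if len(peaks_a) == 0 or len(peaks_b) == 0:
        raise ValueError("both peak sets must be non-empty")
    observed = int(peaks_a.overlaps_any(peaks_b).sum())
    null = np.array(
        [
            int(
                shuffle_intervals(peaks_a, chrom_sizes, blacklist, seed=seed + i)
                .overlaps_any(peaks_b)
                .sum()
            )
            for i in range(n_permutations)
        ]
    )
    expected = float(null.mean())
    row = {
        "category": peaks_b.role or "partner",
        "observed": observed,
        "expected": expected,
        "ratio": observed / expected if expected > 0 else float("inf") if observed else 0.0,
        "overlap_pct": 100.0 * observed / len(peaks_a),
        "p": _empirical_p(observed, null),
        "n_null": n_permutations,
    }
    return EnrichmentReport(df=pd.DataFrame([row]))


def region_matrix(
    track: CoverageTrack,
    regions: IntervalSet,
    flank: int,
    n_columns: int,
    order_by: np.ndarray | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Midpoint-centered signal matrix (regions x columns) + column means.

    Each region contributes one row covering midpoint +/- flank split into
    ``n_columns`` equal windows; windows falling off the chromosome are
    NaN. Rows with an off-chromosome midpoint are dropped with a warning.
    Rows are sorted by descending ``order_by`` when given (e.g. another
    track's row means), else by descending own row mean.
    """
    if flank <= 0 or n_columns < 1:
        raise ValueError("flank must be > 0 and n_columns >= 1")
    df = regions.df
    mid = ((df["start"] + df["end"]) // 2).to_numpy()
    chrom = df["chrom"].to_numpy()
    lengths = np.array([track.chrom_sizes.get(c, 0) for c in chrom])
    ok = (mid >= 0) & (mid < lengths)
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} regions with off-chromosome midpoint dropped")
    mid, chrom, lengths = mid[ok], chrom[ok], lengths[ok]
    if order_by is not None:
        order_by = np.asarray(order_by, dtype=float)[ok]
    edges = np.linspace(-flank, flank, n_columns + 1)
    mat = np.full((len(mid), n_columns), np.nan)
    for j in range(n_columns):
        s = mid + int(round(edges[j]))
        e = mid + int(round(edges[j + 1]))
        inside = (s >= 0) & (e <= lengths)
        if inside.any():
            mat[inside, j] = track.mean_over(chrom[inside], s[inside], e[inside])
    row_means = np.nanmean(mat, axis=1)
    key = order_by if order_by is not None else row_means
    order = np.argsort(-key, kind="stable")
    out = pd.DataFrame(mat[order])
    out.insert(0, "chrom", chrom[order])
    out.insert(1, "mid", mid[order])
    if len(mat):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN edge columns
            col_means = np.nanmean(mat, axis=0)
    else:
        col_means = np.full(n_columns, np.nan)
    return out, col_means
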