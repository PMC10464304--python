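"""Genomic interval sets with 0-based half-open coordinates.

All operations treat intervals as [start, end) on named chromosomes.
Adjacent intervals ([a, b) and [b, c)) never overlap. The container is a
thin wrapper around a pandas DataFrame so downstream code can use either
the typed helpers here or plain DataFrame operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["IntervalSet"]


@dataclass
class IntervalSet:
    """A sorted collection of genomic intervals.

    Parameters
    ----------
    df
        DataFrame with columns ``chrom``, ``start``, ``end`` and optionally
        ``name``. Rows are sorted by (chrom, start, end) on construction.
    role
        Free-text tag describing what the intervals are (peaks, blacklist,
        states, TSS, enhancers, fragments); informational only.
    """

    df: pd.DataFrame
    role: str = ""
    _union_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"interval table missing columns: {sorted(missing)}")
        df = self.df.copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] < 0).any():
            raise ValueError("negative interval start")
        if (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].index[0]
            raise ValueError(f"interval with start >= end at row {bad}")
        self.df = df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(
            drop=True
        )

    @classmethod
    def from_records(cls, records, role: str = "") -> "IntervalSet":
        """Build from an iterable of (chrom, start, end[, name]) tuples."""
        rows = list(records)
        if rows and len(rows[0]) >= 4:
            df = pd.DataFrame(
                [r[:4] for r in rows], columns=["chrom", "start", "end", "name"]
            )
        else:
            df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        return cls(df, role=role)

    @classmethod
    def empty(cls, role: str = "") -> "IntervalSet":
        return cls(pd.DataFrame({"chrom": [], "start": [], "end": []}), role=role)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        cols = ["chrom", "start", "end"] + (
            ["name"] if "name" in self.df.columns else []
        )
        return iter(self.df[cols].itertuples(index=False, name=None))

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def total_bases(self) -> int:
        """Total bases covered by the union of the intervals."""
        return sum(
            int(np.sum(me - ms)) for ms, me, _ in self._unions().values()
        )

    def validate_against(self, chrom_sizes: dict[str, int]) -> None:
        """Raise if any interval extends beyond its chromosome."""
        for chrom, sub in self.df.groupby("chrom", sort=False):
            if chrom not in chrom_sizes:
                raise ValueError(f"chromosome {chrom!r} not in chrom.sizes")
            if int(sub["end"].max()) > chrom_sizes[chrom]:
                raise ValueError(f"interval beyond end of {chrom!r}")

    # -- union machinery -------------------------------------------------

    def _unions(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Per chromosome: merged (starts, ends, cumulative lengths)."""
        if self._union_cache:
            return self._union_cache
        out: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in self.df.groupby("chrom", sort=False):
            s = sub["start"].to_numpy()
            e = sub["end"].to_numpy()
            ms, me = _merge_sorted(s, e)
            cum = np.concatenate([[0], np.cumsum(me - ms)])
            out[chrom] = (ms, me, cum)
        self._union_cache.update(out)
        return self._union_cache

    def merged(self, role: str | None = None) -> "IntervalSet":
        """Union of the intervals as a new sorted, non-overlapping set."""
        recs = []
        for chrom, (ms, me, _) in self._unions().items():
            recs.extend((chrom, int(a), int(b)) for a, b in zip(ms, me))
        out = IntervalSet.from_records(recs) if recs else IntervalSet.empty()
        out.role = self.role if role is None else role
        return out

    def overlap_bp(
        self, chrom: np.ndarray | list, start: np.ndarray, end: np.ndarray
    ) -> np.ndarray:
        """Bases of each query interval covered by the union of this set."""
        chrom = np.asarray(chrom)
        start = np.asarray(start, dtype=np.int64)
        end = np.asarray(end, dtype=np.int64)
        out = np.zeros(len(start), dtype=np.int64)
        unions = self._unions()
        for c in np.unique(chrom):
            if c not in unions:
                continue
            ms, me, cum = unions[c]
            mask = chrom == c
            s, e = start[mask], end[mask]
            lo = np.searchsorted(me, s, side="right")
            hi = np.searchsorted(ms, e, side="left")
            full = cum[hi] - cum[lo]
            has = hi > lo
            lo_c = np.where(has, lo, 0)
            hi_c = np.where(has, hi - 1, 0)
            trim_left = np.maximum(0, s - ms[lo_c])
            trim_right = np.maximum(0, me[hi_c] - e)
            out[mask] = np.where(has, full - trim_left - trim_right, 0)
        return out

    def overlaps_any(self, other: "IntervalSet") -> np.ndarray:
        """Boolean per interval of *self*: overlaps >= 1 bp of *other*."""
        if len(self.df) == 0:
            return np.zeros(0, dtype=bool)
        return (
            other.overlap_bp(
                self.df["chrom"].to_numpy(),
                self.df["start"].to_numpy(),
                self.df["end"].to_numpy(),
            )
            > 0
        )


def _merge_sorted(starts: np.ndarray, ends: np.ndarray):
    """Merge intervals already sorted by start into a disjoint union."""
    if len(starts) == 0:
        return starts, ends
    ms, me = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= me[-1]:  # touch (s == end) is NOT an overlap but union-merging
            if e > me[-1]:
                me[-1] = e
        else:
            ms.append(s)
            me.append(e)
    return np.asarray(ms, dtype=np.int64), np.asarray(me, dtype=np.int64)
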