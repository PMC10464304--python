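"""Run-length coverage tracks over a genome.

A :class:`CoverageTrack` stores, per chromosome, a complete piecewise-
constant partition of [0, L): breakpoint array ``bounds`` of length m+1
(``bounds[0] == 0``, ``bounds[-1] == L``) and a value array of length m.
Gaps in the source bedGraph become explicit zero-valued runs, so every
base has exactly one value and per-base arithmetic (pooling, log-ratios)
is exact without densifying the genome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CoverageTrack", "pool_tracks", "log2_ratio_track"]


@dataclass
class CoverageTrack:
    chrom_sizes: dict[str, int]
    data: dict[str, tuple[np.ndarray, np.ndarray]]  # chrom -> (bounds, values)

    @classmethod
    def from_records(
        cls, records, chrom_sizes: dict[str, int]
    ) -> "CoverageTrack":
        """Build from (chrom, start, end, value) records.

        Records must be non-overlapping within a chromosome; gaps are
        filled with zeros. Raises on out-of-bounds or overlapping input.
        """
        per_chrom: dict[str, list] = {c: [] for c in chrom_sizes}
        for chrom, start, end, value in records:
            if chrom not in chrom_sizes:
                raise ValueError(f"chromosome {chrom!r} not in chrom.sizes")
            per_chrom[chrom].append((int(start), int(end), float(value)))
        data = {}
        for chrom, L in chrom_sizes.items():
            rows = sorted(per_chrom[chrom])
            bounds = [0]
            values = []
            for start, end, value in rows:
                if start < 0 or end > L or start >= end:
                    raise ValueError(
                        f"bad interval [{start}, {end}) on {chrom!r} (length {L})"
                    )
                if start < bounds[-1]:
                    raise ValueError(f"overlapping records on {chrom!r} at {start}")
                if not np.isfinite(value):
                    raise ValueError(f"non-finite value on {chrom!r} at {start}")
                if start > bounds[-1]:
                    bounds.append(start)
                    values.append(0.0)
                bounds.append(end)
                values.append(value)
            if bounds[-1] < L:
                bounds.append(L)
                values.append(0.0)
            data[chrom] = (
                np.asarray(bounds, dtype=np.int64),
                np.asarray(values, dtype=np.float64),
            )
        return cls(dict(chrom_sizes), data)._coalesced()

    @classmethod
    def from_dense(
        cls,
        dense: dict[str, np.ndarray],
        chrom_sizes: dict[str, int],
        resolution: int = 1,
    ) -> "CoverageTrack":
        """Build from per-chromosome dense arrays sampled at ``resolution`` bp.

        The final element of each array may describe a short trailing bin.
        """
        data = {}
        for chrom, L in chrom_sizes.items():
            vals = np.asarray(dense[chrom], dtype=np.float64)
            n = len(vals)
            if (n - 1) * resolution >= L or n * resolution < L:
                raise ValueError(f"dense array length mismatch for {chrom!r}")
            bounds = np.minimum(np.arange(n + 1, dtype=np.int64) * resolution, L)
            data[chrom] = (bounds, vals)
        return cls(dict(chrom_sizes), data)._coalesced()

    @classmethod
    def constant(cls, value: float, chrom_sizes: dict[str, int]) -> "CoverageTrack":
        data = {
            c: (np.array([0, L], dtype=np.int64), np.array([float(value)]))
            for c, L in chrom_sizes.items()
        }
        return cls(dict(chrom_sizes), data)

    def _coalesced(self) -> "CoverageTrack":
        """Merge adjacent runs of identical value (canonical form)."""
        data = {}
        for chrom, (bounds, values) in self.data.items():
            if len(values) <= 1:
                data[chrom] = (bounds, values)
                continue
            keep = np.concatenate([[True], values[1:] != values[:-1]])
            new_vals = values[keep]
            idx = np.flatnonzero(keep)
            new_bounds = np.concatenate([bounds[idx], [bounds[-1]]])
            data[chrom] = (new_bounds, new_vals)
        return CoverageTrack(self.chrom_sizes, data)

    # -- queries ---------------------------------------------------------

    def value_at(self, chrom: str, pos: int) -> float:
        bounds, values = self.data[chrom]
        i = int(np.searchsorted(bounds, pos, side="right")) - 1
        return float(values[min(i, len(values) - 1)])

    def integral(self, chrom: str, start: np.ndarray, end: np.ndarray) -> np.ndarray:
        """Exact integral of the track over [start, end) intervals."""
        bounds, values = self.data[chrom]
        cum = np.concatenate([[0.0], np.cumsum(values * np.diff(bounds))])

        def at(x):
            x = np.asarray(x, dtype=np.int64)
            i = np.clip(
                np.searchsorted(bounds, x, side="right") - 1, 0, len(values) - 1
            )
            return cum[i] + values[i] * (x - bounds[i])

        return at(end) - at(start)

    def mean_over(
        self, chrom: np.ndarray | list, start: np.ndarray, end: np.ndarray
    ) -> np.ndarray:
        """Base-weighted mean over each query interval (0 off-track)."""
        chrom = np.asarray(chrom)
        start = np.asarray(start, dtype=np.int64)
        end = np.asarray(end, dtype=np.int64)
        out = np.zeros(len(start), dtype=np.float64)
        for c in np.unique(chrom):
            mask = chrom == c
            if c not in self.data:
                continue
            out[mask] = self.integral(c, start[mask], end[mask]) / (
                end[mask] - start[mask]
            )
        return out

    def to_records(self, include_zero: bool = False):
        """Yield (chrom, start, end, value) runs; zero runs skipped by default."""
        for chrom in self.chrom_sizes:
            bounds, values = self.data[chrom]
            for i, v in enumerate(values):
                if include_zero or v != 0.0:
                    yield chrom, int(bounds[i]), int(bounds[i + 1]), float(v)

    def to_dense(self, resolution: int = 1) -> dict[str, np.ndarray]:
        """Per-chromosome array of base-weighted means per resolution bin."""
        out = {}
        for chrom, L in self.chrom_sizes.items():
            n = -(-L // resolution)
            starts = np.arange(n, dtype=np.int64) * resolution
            ends = np.minimum(starts + resolution, L)
            out[chrom] = self.integral(chrom, starts, ends) / (ends - starts)
        return out

    def map_values(self, fn) -> "CoverageTrack":
        data = {
            c: (bounds.copy(), np.asarray(fn(values), dtype=np.float64))
            for c, (bounds, values) in self.data.items()
        }
        return CoverageTrack(self.chrom_sizes, data)._coalesced()


def _check_same_genome(tracks) -> dict[str, int]:
    first = tracks[0].chrom_sizes
    for t in tracks[1:]:
        if t.chrom_sizes != first:
            a, b = set(first), set(t.chrom_sizes)
            raise ValueError(
                "tracks cover different genomes; "
                f"chromosome set difference: {sorted(a ^ b)}"
            )
    return first


def _aligned(tracks):
    """Common breakpoints + per-track values per chromosome."""
    chrom_sizes = _check_same_genome(tracks)
    for chrom in chrom_sizes:
        bounds = tracks[0].data[chrom][0]
        for t in tracks[1:]:
            bounds = np.union1d(bounds, t.data[chrom][0])
        cols = []
        for t in tracks:
            tb, tv = t.data[chrom]
            idx = np.clip(
                np.searchsorted(tb, bounds[:-1], side="right") - 1, 0, len(tv) - 1
            )
            cols.append(tv[idx])
        yield chrom, bounds, cols


def pool_tracks(tracks: list[CoverageTrack]) -> CoverageTrack:
    """Per-base arithmetic mean of replicate tracks."""
    if len(tracks) < 2:
        raise ValueError("pooling requires >= 2 tracks")
    data = {}
    for chrom, bounds, cols in _aligned(tracks):
        data[chrom] = (bounds, np.mean(cols, axis=0))
    return CoverageTrack(tracks[0].chrom_sizes, data)._coalesced()


def log2_ratio_track(
    chip: CoverageTrack, input_: CoverageTrack, pseudocount: float = 1.0
) -> CoverageTrack:
    """Per-base log2((chip + pc) / (input + pc)) track."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    data = {}
    for chrom, bounds, (a, b) in _aligned([chip, input_]):
        data[chrom] = (bounds, np.log2((a + pseudocount) / (b + pseudocount)))
    return CoverageTrack(chip.chrom_sizes, data)._coalesced()
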