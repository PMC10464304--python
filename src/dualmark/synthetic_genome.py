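"""Synthetic toy genome with planted double-mark structure.

Generates everything the co-occurrence pipeline consumes, with known
ground truth:

* megabase-scale broad H3K9me2 domains (smoothed-boxcar signal, no read
  modeling — the pipeline consumes normalized coverage);
* kilobase-scale H3K4me1 peaks scattered over the genome, a fraction of
  which land inside K9me2 domains;
* smaller H3K9me3 domains;
* a reader-domain (TTD) track coupled to the *product* of H3K4me1 signal
  and the K9me2/K9me3 domain indicators, plus an additive K9me2 term and
  noise — the binding rule the double-mark model predicts;
* a chromatin-state partition, TSS annotations and an enhancer->gene map;
* a probe-level expression table with a planted set of genes that are
  unchanged under wild-type rescue but upregulated under a reader-dead
  (TTD*) rescue, whose enhancers carry elevated H3K4me1.

All randomness flows from one top-level seed through named substreams so
every artifact is reproducible bit-for-bit.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import IntervalSet
from .tracks import CoverageTrack

__all__ = [
    "GenomeSpec",
    "MarkSpec",
    "CouplingSpec",
    "ExpressionSpec",
    "SyntheticTracks",
    "generate_tracks",
    "generate_annotations",
    "generate_expression",
    "make_fragment_classes",
]


def _substream(seed: int, name: str) -> np.random.Generator:
    # process-independent substream: crc32 is stable, unlike builtin hash()
    tag = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([seed, tag]))


@dataclass
class GenomeSpec:
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 2_500_000, "chr2": 2_500_000}
    )
    resolution: int = 10  # bp per emitted track bin
    seed: int = 0

    def __post_init__(self):
        if any(L <= 0 for L in self.chrom_sizes.values()):
            raise ValueError("chromosome lengths must be > 0")
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")

    @property
    def total_bases(self) -> int:
        return sum(self.chrom_sizes.values())


@dataclass
class MarkSpec:
    """Feature geometry and signal model for one histone mark."""

    width_min: int
    width_max: int
    coverage_fraction: float
    level: float  # within-feature plateau signal
    background: float
    noise_sd: float
    smooth_bp: int  # moving-average window applied to the feature indicator

    def __post_init__(self):
        if not 0 <= self.coverage_fraction < 1:
            raise ValueError("coverage_fraction must be in [0, 1)")
        if self.level < 0 or self.background < 0 or self.noise_sd < 0:
            raise ValueError("signal levels must be >= 0")
        if self.width_min <= 0 or self.width_max < self.width_min:
            raise ValueError("bad width range")


def default_marks() -> dict[str, MarkSpec]:
    """Scaled-down defaults for the 5 Mb toy genome.

    Broad K9me2 blocks are shrunk from the megabase scale in proportion to
    the genome so several independent domains fit per chromosome; K4me1
    keeps its real kilobase peak scale.
    """
    return {
        "K9me2": MarkSpec(200_000, 600_000, 0.40, 4.0, 0.20, 0.30, 5_000),
        "K4me1": MarkSpec(500, 2_000, 0.02, 6.0, 0.10, 0.30, 200),
        "K9me3": MarkSpec(50_000, 200_000, 0.10, 3.0, 0.10, 0.30, 2_000),
    }


@dataclass
class CouplingSpec:
    """TTD track = alpha*K4me1*1[K9me2 dom] + gamma*K4me1*1[K9me3 dom] + beta*K9me2 + noise."""

    alpha: float = 1.0
    beta: float = 0.15
    gamma: float = 0.5
    noise_sd: float = 0.20

    def __post_init__(self):
        if min(self.alpha, self.beta, self.gamma, self.noise_sd) < 0:
            raise ValueError("coupling weights and noise must be >= 0")


@dataclass
class SyntheticTracks:
    genome: GenomeSpec
    tracks: dict[str, CoverageTrack]  # K9me2, K4me1, K9me3, TTD, input
    truth: dict[str, IntervalSet]  # {mark}_features truth intervals


def _place_features(
    rng: np.random.Generator,
    chrom_sizes: dict[str, int],
    spec: MarkSpec,
    max_tries: int = 20_000,
) -> IntervalSet:
    """Non-overlapping features reaching the target coverage fraction.

    The final feature is trimmed so the realized covered-base total equals
    the target exactly (never below the minimum width).
    """
    total = sum(chrom_sizes.values())
    target = int(round(spec.coverage_fraction * total))
    chroms = list(chrom_sizes)
    weights = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    covered = 0
    tries = 0
    while covered < target:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not reach target coverage; lower the fraction")
        width = int(rng.integers(spec.width_min, spec.width_max + 1))
        width = max(min(width, target - covered), min(spec.width_min, target - covered))
        c = chroms[rng.choice(len(chroms), p=weights)]
        if chrom_sizes[c] < width:
            continue
        s = int(rng.integers(0, chrom_sizes[c] - width + 1))
        e = s + width
        if any(s < pe and ps < e for ps, pe in placed[c]):
            continue
        placed[c].append((s, e))
        covered += width
    recs = [(c, s, e) for c, ivs in placed.items() for s, e in sorted(ivs)]
    return IntervalSet.from_records(recs) if recs else IntervalSet.empty()


def _indicator(features: IntervalSet, chrom: str, length: int, resolution: int) -> np.ndarray:
    n = -(-length // resolution)
    out = np.zeros(n)
    sub = features.df[features.df["chrom"] == chrom]
    for s, e in zip(sub["start"], sub["end"]):
        out[s // resolution : -(-e // resolution)] = 1.0
    return out


def _smooth(x: np.ndarray, window_bins: int) -> np.ndarray:
    if window_bins <= 1:
        return x
    kernel = np.ones(window_bins) / window_bins
    return np.convolve(x, kernel, mode="same")


def generate_tracks(
    genome: GenomeSpec,
    marks: dict[str, MarkSpec] | None = None,
    coupling: CouplingSpec | None = None,
) -> SyntheticTracks:
    """Generate the mark, reader and input coverage tracks plus truth."""
    marks = default_marks() if marks is None else marks
    coupling = CouplingSpec() if coupling is None else coupling
    res = genome.resolution

    truth: dict[str, IntervalSet] = {}
    for name, spec in marks.items():
        rng = _substream(genome.seed, f"features/{name}")
        truth[name] = (
            _place_features(rng, genome.chrom_sizes, spec)
            if spec.coverage_fraction > 0
            else IntervalSet.empty()
        )
        truth[name].role = "peaks" if spec.width_max < 10_000 else "domains"

    dense: dict[str, dict[str, np.ndarray]] = {name: {} for name in marks}
    dense["TTD"] = {}
    dense["input"] = {}
    for chrom, length in genome.chrom_sizes.items():
        indicators = {}
        for name, spec in marks.items():
            rng = _substream(genome.seed, f"signal/{name}/{chrom}")
            ind = _indicator(truth[name], chrom, length, res)
            indicators[name] = ind
            sig = spec.background + spec.level * _smooth(ind, max(1, spec.smooth_bp // res))
            if spec.noise_sd > 0:
                sig = sig + rng.normal(0, spec.noise_sd, size=len(sig))
            dense[name][chrom] = np.maximum(sig, 0.0)
        rng = _substream(genome.seed, f"signal/TTD/{chrom}")
        ttd = (
            coupling.alpha * dense["K4me1"][chrom] * indicators["K9me2"]
            + coupling.gamma * dense["K4me1"][chrom] * indicators["K9me3"]
            + coupling.beta * dense["K9me2"][chrom]
        )
        if coupling.noise_sd > 0:
            ttd = ttd + rng.normal(0, coupling.noise_sd, size=len(ttd))
        dense["TTD"][chrom] = np.maximum(ttd, 0.0)
        rng = _substream(genome.seed, f"signal/input/{chrom}")
        n = -(-length // res)
        dense["input"][chrom] = np.maximum(1.0 + rng.normal(0, 0.1, size=n), 0.0)

    tracks = {
        name: CoverageTrack.from_dense(arr, genome.chrom_sizes, res)
        for name, arr in dense.items()
    }
    return SyntheticTracks(genome=genome, tracks=tracks, truth=truth)


# -- fragment classes (the three-way planted construction) ----------------


def make_fragment_classes(
    sim: SyntheticTracks,
    n_background_segments: int = 120,
    segment_width: tuple[int, int] = (600, 1_500),
    seed_name: str = "fragment-classes",
):
    """Build a synthetic reader-peak set with three planted classes.

    Classes: K4me1 peaks inside K9me2 domains ("double"), K9me2-domain
    segments without K4me1 ("k9me2_only"), and K4me1 peaks outside the
    domains ("k4me1_only"). Returns (peak IntervalSet, class regions dict)
    for downstream fragmentation and truth labeling.
    """
    rng = _substream(sim.genome.seed, seed_name)
    peaks = sim.truth["K4me1"]
    domains = sim.truth["K9me2"]
    inside = peaks.overlaps_any(domains)
    double = IntervalSet(peaks.df[inside][["chrom", "start", "end"]])
    k4_only = IntervalSet(peaks.df[~inside][["chrom", "start", "end"]])

    segs = []
    guard = 0
    dom_rows = domains.df
    while len(segs) < n_background_segments and guard < 50 * n_background_segments:
        guard += 1
        row = dom_rows.iloc[int(rng.integers(0, len(dom_rows)))]
        w = int(rng.integers(segment_width[0], segment_width[1] + 1))
        if row["end"] - row["start"] <= w:
            continue
        s = int(rng.integers(row["start"], row["end"] - w))
        if peaks.overlap_bp([row["chrom"]], np.array([s]), np.array([s + w]))[0] > 0:
            continue
        if any(c == row["chrom"] and s < pe and ps < s + w for c, ps, pe in segs):
            continue
        segs.append((row["chrom"], s, s + w))
    k9_only = IntervalSet.from_records(segs)

    regions = {"double": double, "k9me2_only": k9_only, "k4me1_only": k4_only}
    all_recs = [
        (c, s, e)
        for part in regions.values()
        for c, s, e in zip(part.df["chrom"], part.df["start"], part.df["end"])
    ]
    peak_set = IntervalSet.from_records(all_recs, role="peaks")
    return peak_set, regions


def label_fragments(fragments: IntervalSet, regions: dict[str, IntervalSet]) -> np.ndarray:
    """Truth class per fragment: the region class covering most of it."""
    chrom = fragments.df["chrom"].to_numpy()
    start = fragments.df["start"].to_numpy()
    end = fragments.df["end"].to_numpy()
    names = list(regions)
    ov = np.stack([regions[n].overlap_bp(chrom, start, end) for n in names])
    return np.asarray(names, dtype=object)[np.argmax(ov, axis=0)]


# -- annotations ----------------------------------------------------------


def generate_annotations(
    genome: GenomeSpec,
    k4me1_peaks: IntervalSet,
    n_genes: int = 400,
    n_enhancers: int = 200,
    enhancer_width: int = 800,
    tss_flank: int = 1_000,
    placement_fidelity: float = 1.0,
):
    """Chromatin-state partition, TSS set, and enhancer->gene map.

    States partition every chromosome without gaps or overlaps into
    Enhancer / FlankingTSS / Quiescent. Each enhancer is centered on a
    planted K4me1 peak with probability ``placement_fidelity`` and placed
    uniformly at random otherwise.

    Returns (states IntervalSet, tss IntervalSet, enhancer_map DataFrame).
    """
    if not 0 <= placement_fidelity <= 1:
        raise ValueError("placement_fidelity must be in [0, 1]")
    rng = _substream(genome.seed, "annotations")
    chroms = list(genome.chrom_sizes)
    weights = np.array([genome.chrom_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()

    # genes / TSSs
    tss_recs = []
    for g in range(n_genes):
        c = chroms[rng.choice(len(chroms), p=weights)]
        pos = int(rng.integers(tss_flank, genome.chrom_sizes[c] - tss_flank))
        tss_recs.append((c, pos, pos + 1, f"gene{g:04d}"))
    tss = IntervalSet.from_records(tss_recs, role="TSS")

    # enhancers: on-peak with probability = fidelity
    peak_rows = k4me1_peaks.df
    enh_recs = []
    for i in range(n_enhancers):
        on_peak = len(peak_rows) > 0 and rng.random() < placement_fidelity
        if on_peak:
            row = peak_rows.iloc[int(rng.integers(0, len(peak_rows)))]
            center = int((row["start"] + row["end"]) // 2)
            c = row["chrom"]
        else:
            c = chroms[rng.choice(len(chroms), p=weights)]
            center = int(rng.integers(enhancer_width, genome.chrom_sizes[c] - enhancer_width))
        s = max(0, center - enhancer_width // 2)
        e = min(genome.chrom_sizes[c], s + enhancer_width)
        gene = f"gene{int(rng.integers(0, n_genes)):04d}"
        enh_recs.append((c, s, e, f"enh{i:04d}", gene))
    enhancer_map = pd.DataFrame(
        enh_recs, columns=["chrom", "start", "end", "enhancer_id", "gene"]
    )

    # state partition: paint Quiescent, then TSS flanks, then enhancers
    states = []
    for chrom, length in genome.chrom_sizes.items():
        layers = [("Quiescent", 0, length)]
        paint = []
        for _, row in tss.df[tss.df["chrom"] == chrom].iterrows():
            paint.append(("FlankingTSS", max(0, row["start"] - tss_flank),
                          min(length, row["end"] + tss_flank)))
        for rec in enh_recs:
            if rec[0] == chrom:
                paint.append(("Enhancer", rec[1], rec[2]))
        states.extend(_flatten_states(layers + paint, length, chrom))
    state_set = IntervalSet.from_records(states, role="states")
    return state_set, tss, enhancer_map


def _flatten_states(layers, length: int, chrom: str):
    """Later layers overwrite earlier ones; emit a gap-free partition."""
    cuts = sorted({0, length} | {s for _, s, _ in layers} | {e for _, _, e in layers})
    out = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        label = "Quiescent"
        for name, s, e in layers:
            if s <= a and b <= e:
                label = name
        out.append((chrom, a, b, label))
    # merge adjacent same-label runs
    merged = [out[0]]
    for rec in out[1:]:
        if rec[3] == merged[-1][3] and rec[1] == merged[-1][2]:
            merged[-1] = (chrom, merged[-1][1], rec[2], rec[3])
        else:
            merged.append(rec)
    return merged


# -- expression -----------------------------------------------------------


@dataclass
class ExpressionSpec:
    n_genes: int = 400
    probes_per_gene: tuple[int, int] = (1, 3)
    n_planted: int = 115  # TTD*-dependent genes
    n_wt_up: int = 30
    n_wt_down: int = 30
    planted_lfc: float = 2.0  # log2 FC of planted genes under TTD* rescue
    wt_lfc: float = 1.5  # |log2 FC| of WT-responsive genes in both channels
    noise_sd: float = 0.0  # probe-level log2 FC noise
    enhancer_shift: float = 1.0  # +delta on planted genes' enhancer K4me1
    enhancer_mu: float = 2.0
    enhancer_sd: float = 0.5

    def __post_init__(self):
        if self.n_planted + self.n_wt_up + self.n_wt_down > self.n_genes:
            raise ValueError("planted and WT-responsive sets exceed the gene universe")


@dataclass
class ExpressionFixture:
    probe_table: pd.DataFrame  # probe_id, gene, lfc_wt, lfc_ttdstar
    enhancer_table: pd.DataFrame  # enhancer_id, gene, k4me1, k9me2
    planted: set[str]
    wt_up: set[str]
    wt_down: set[str]


def generate_expression(
    spec: ExpressionSpec,
    enhancer_map: pd.DataFrame | None = None,
    seed: int = 0,
) -> ExpressionFixture:
    """Probe-level log2 fold-change table with a planted reader-dependent set.

    The planted genes are non-responsive under WT rescue but upregulated
    under the reader-dead (TTD*) rescue, and their enhancers carry K4me1
    elevated by ``enhancer_shift``; WT-responsive genes respond in both
    channels and are disjoint from the planted set by construction.
    """
    rng = np.random.default_rng(seed)
    genes = [f"gene{g:04d}" for g in range(spec.n_genes)]
    perm = rng.permutation(spec.n_genes)
    planted = {genes[i] for i in perm[: spec.n_planted]}
    wt_up = {genes[i] for i in perm[spec.n_planted : spec.n_planted + spec.n_wt_up]}
    wt_down = {
        genes[i]
        for i in perm[
            spec.n_planted + spec.n_wt_up : spec.n_planted + spec.n_wt_up + spec.n_wt_down
        ]
    }

    rows = []
    probe_i = 0
    for g in genes:
        n_probes = int(rng.integers(spec.probes_per_gene[0], spec.probes_per_gene[1] + 1))
        if g in wt_up:
            wt_mu, ttd_mu = spec.wt_lfc, spec.wt_lfc
        elif g in wt_down:
            wt_mu, ttd_mu = -spec.wt_lfc, -spec.wt_lfc
        elif g in planted:
            wt_mu, ttd_mu = 0.0, spec.planted_lfc
        else:
            wt_mu, ttd_mu = 0.0, 0.0
        for _ in range(n_probes):
            rows.append(
                {
                    "probe_id": f"p{probe_i:06d}",
                    "gene": g,
                    "lfc_wt": wt_mu + rng.normal(0, spec.noise_sd) if spec.noise_sd else wt_mu,
                    "lfc_ttdstar": ttd_mu + rng.normal(0, spec.noise_sd)
                    if spec.noise_sd
                    else ttd_mu,
                }
            )
            probe_i += 1
    probe_table = pd.DataFrame(rows)

    if enhancer_map is None:
        enhancer_map = pd.DataFrame(
            {"enhancer_id": [f"enh{i:04d}" for i in range(spec.n_genes)], "gene": genes}
        )
    k4 = rng.normal(spec.enhancer_mu, spec.enhancer_sd, size=len(enhancer_map))
    k9 = rng.normal(spec.enhancer_mu, spec.enhancer_sd, size=len(enhancer_map))
    shift = enhancer_map["gene"].isin(planted).to_numpy() * spec.enhancer_shift
    enhancer_table = pd.DataFrame(
        {
            "enhancer_id": enhancer_map["enhancer_id"],
            "gene": enhancer_map["gene"],
            "k4me1": np.maximum(k4 + shift, 0.0),
            "k9me2": np.maximum(k9, 0.0),
        }
    )
    return ExpressionFixture(
        probe_table=probe_table,
        enhancer_table=enhancer_table,
        planted=planted,
        wt_up=wt_up,
        wt_down=wt_down,
    )
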