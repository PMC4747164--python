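"""Summit-centred read-density profiling.

The profiling pipeline follows a fixed order, enforced through the stage
flag carried by every :class:`BinTrack`:

    shift -> bin -> per-million -> input-subtracted -> quantile -> matrix/rank

Reads are shifted 3' by half the library's mean fragment size so the
shifted position estimates the fragment midpoint, counted into 25-bp
non-overlapping bins, scaled to reads per million, input-corrected by
per-bin subtraction, and quantile-normalized across samples.  Summit
windows of +/-20 bins (+/-500 bp) around each peak summit give the
mean-read-density profile and its ranked heat-map matrix.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .genomic_io import GenomeSequence, Peak, ReadAlignment

logger = logging.getLogger(__name__)

__all__ = [
    "ProfileConfig",
    "BinTrack",
    "SummitMatrix",
    "shift_reads",
    "bin_and_normalize",
    "subtract_input",
    "quantile_normalize",
    "summit_matrix",
    "rank_transform",
    "write_wiggle",
]

#: per-library mean fragment sizes, bp (single-end libraries)
DEFAULT_FRAGMENT_SIZES = {"WT": 171, "daf-2": 158, "daf-16;daf-2": 200}

STAGES = ("raw", "per-million", "input-subtracted", "quantile", "rank")


@dataclass
class ProfileConfig:
    bin_width: int = 25
    flank_bins: int = 20
    fragment_sizes: dict = field(default_factory=lambda: dict(DEFAULT_FRAGMENT_SIZES))
    normalization_scale: float = 1e6
    shift_mode: str = "half"  # "half" (fragment midpoint) or "full"
    clip_negative: bool = False

    def __post_init__(self) -> None:
        if self.bin_width < 1 or self.flank_bins < 1:
            raise ValueError("bin_width and flank_bins must be >= 1")
        if self.shift_mode not in ("half", "full"):
            raise ValueError("shift_mode must be 'half' or 'full'")


@dataclass
class BinTrack:
    """Fixed-width binned genome-wide signal for one sample."""

    sample: str
    bin_width: int
    values: dict[str, np.ndarray]
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    def concatenated(self) -> np.ndarray:
        return np.concatenate([self.values[c] for c in sorted(self.values)])

    @property
    def n_bins(self) -> int:
        return sum(v.size for v in self.values.values())


@dataclass
class SummitMatrix:
    """Per-peak summit-centred windows, rows ranked by centre-bin value."""

    peak_ids: list[str]
    offsets: np.ndarray  # signed bin offsets, length 2*flank+1
    matrix: np.ndarray  # (n_peaks_kept, 2*flank+1)
    n_dropped: int = 0

    @property
    def column_means(self) -> np.ndarray:
        return self.matrix.mean(axis=0)

    def to_tsv(self, path: str) -> None:
        header = "peak_id\t" + "\t".join(str(int(o)) for o in self.offsets)
        with open(path, "w") as fh:
            fh.write(header + "\n")
            for pid, row in zip(self.peak_ids, self.matrix):
                fh.write(pid + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def shift_reads(
    reads: list[ReadAlignment],
    fragment_size: int,
    chrom_lengths: dict[str, int] | None = None,
    mode: str = "half",
) -> dict[str, np.ndarray]:
    """Shift each read 3' to its fragment-midpoint estimate.

    Plus-strand reads move to ``start + round(shift)``, minus-strand reads
    to ``end - 1 - round(shift)`` where the shift is half the mean fragment
    size (or the full size with ``mode='full'``).  Positions are clamped to
    chromosome bounds when lengths are given.
    """
    shift = round(fragment_size / 2) if mode == "half" else round(fragment_size)
    by_chrom: dict[str, list[int]] = {}
    for r in reads:
        pos = r.start + shift if r.strand == "+" else r.end - 1 - shift
        by_chrom.setdefault(r.chrom, []).append(pos)
    out = {}
    for chrom, positions in by_chrom.items():
        arr = np.asarray(positions, dtype=np.int64)
        if chrom_lengths is not None:
            arr = np.clip(arr, 0, chrom_lengths[chrom] - 1)
        out[chrom] = arr
    return out


def bin_and_normalize(
    positions: dict[str, np.ndarray],
    genome,
    config: ProfileConfig,
    total_unique_reads: int,
    sample: str = "",
) -> BinTrack:
    """Count shifted positions into bins and scale to reads per million."""
    if total_unique_reads <= 0:
        raise ValueError("total_unique_reads must be positive")
    lengths = genome.lengths if isinstance(genome, GenomeSequence) else dict(genome)
    values = {}
    for chrom, length in lengths.items():
        n_bins = math.ceil(length / config.bin_width)
        pos = positions.get(chrom, np.empty(0, dtype=np.int64))
        if pos.size and (pos.min() < 0 or pos.max() >= length):
            raise ValueError(f"position outside chromosome {chrom}")
        counts = np.bincount(pos // config.bin_width, minlength=n_bins).astype(float)
        values[chrom] = counts * config.normalization_scale / total_unique_reads
    return BinTrack(sample=sample, bin_width=config.bin_width, values=values,
                    stage="per-million")


def subtract_input(chip: BinTrack, input_track: BinTrack, clip_negative: bool = False) -> BinTrack:
    """Per-bin ChIP minus input; negative values are retained by default
    (quantile normalization follows and would be distorted by clipping)."""
    if chip.stage != "per-million" or input_track.stage != "per-million":
        raise ValueError("subtract_input requires two per-million tracks")
    if chip.bin_width != input_track.bin_width or set(chip.values) != set(input_track.values):
        raise ValueError("tracks are not on the same binned genome")
    values = {}
    for chrom, v in chip.values.items():
        w = input_track.values[chrom]
        if v.size != w.size:
            raise ValueError(f"bin-vector length mismatch on {chrom}")
        diff = v - w
        values[chrom] = np.clip(diff, 0, None) if clip_negative else diff
    return BinTrack(sample=chip.sample, bin_width=chip.bin_width, values=values,
                    stage="input-subtracted")


def quantile_normalize(tracks: list[BinTrack]) -> list[BinTrack]:
    """Classic quantile normalization over the genome-wide bin vectors.

    The value at rank k in each sample is replaced by the across-sample
    mean of the k-th order statistics; tied values receive the mean of the
    replacement values their span covers.
    """
    if len(tracks) < 2:
        raise ValueError("quantile normalization needs >= 2 tracks")
    stages = {t.stage for t in tracks}
    if len(stages) != 1:
        raise ValueError(f"tracks at mixed stages {stages}")
    mats = [t.concatenated() for t in tracks]
    n = mats[0].size
    if any(m.size != n for m in mats):
        raise ValueError("tracks have different genome-wide lengths")

    target = np.mean([np.sort(m) for m in mats], axis=0)
    out = []
    for track, v in zip(tracks, mats):
        order = np.argsort(v, kind="stable")
        normalized = np.empty(n)
        # ties: average the target values spanned by each tied run
        sv = v[order]
        boundaries = np.flatnonzero(np.diff(sv)) + 1
        starts = np.concatenate([[0], boundaries])
        sums = np.add.reduceat(target, starts)
        counts = np.diff(np.concatenate([starts, [n]]))
        run_means = np.repeat(sums / counts, counts)
        normalized[order] = run_means
        out.append(_rebuild(track, normalized, "quantile"))
    return out


def _rebuild(track: BinTrack, flat: np.ndarray, stage: str) -> BinTrack:
    values = {}
    i = 0
    for chrom in sorted(track.values):
        size = track.values[chrom].size
        values[chrom] = flat[i : i + size].copy()
        i += size
    return BinTrack(sample=track.sample, bin_width=track.bin_width, values=values, stage=stage)


def summit_matrix(track: BinTrack, peaks: list[Peak], config: ProfileConfig) -> SummitMatrix:
    """Collect the +/-``flank_bins`` window around each summit's bin.

    Rows are sorted by centre-bin value, descending ("ranked" heat-map
    order).  Peaks whose window would cross a chromosome edge are dropped
    and counted.
    """
    flank = config.flank_bins
    offsets = np.arange(-flank, flank + 1)
    rows, ids = [], []
    dropped = 0
    for p in peaks:
        vec = track.values.get(p.chrom)
        if vec is None:
            dropped += 1
            continue
        center = p.summit // track.bin_width
        if center - flank < 0 or center + flank >= vec.size:
            dropped += 1
            continue
        rows.append(vec[center - flank : center + flank + 1])
        ids.append(p.peak_id)
    if dropped:
        logger.info("dropped %d peaks with windows beyond chromosome edges", dropped)
    if not rows:
        return SummitMatrix(peak_ids=[], offsets=offsets,
                            matrix=np.empty((0, 2 * flank + 1)), n_dropped=dropped)
    matrix = np.vstack(rows)
    order = np.argsort(-matrix[:, flank], kind="stable")
    return SummitMatrix(
        peak_ids=[ids[i] for i in order],
        offsets=offsets,
        matrix=matrix[order],
        n_dropped=dropped,
    )


def rank_transform(track: BinTrack) -> BinTrack:
    """Replace each bin by its genome-wide fractional rank in (0, 1].

    Ties get the mean rank, so the output is invariant under any strictly
    increasing transform of the input values.
    """
    from scipy.stats import rankdata

    flat = track.concatenated()
    ranks = rankdata(flat, method="average") / flat.size
    return _rebuild(track, ranks, "rank")


def write_wiggle(track: BinTrack, path: str) -> None:
    """Fixed-step wiggle export (1-based starts, one value per bin)."""
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{track.sample}"\n')
        for chrom in sorted(track.values):
            fh.write(f"fixedStep chrom={chrom} start=1 step={track.bin_width} "
                     f"span={track.bin_width}\n")
            fh.write("\n".join(f"{v:.6g}" for v in track.values[chrom]) + "\n")
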