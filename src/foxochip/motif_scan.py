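"""PSSM scanning against a Markov background, enrichment and motif spacing.

Scores are log-likelihood ratios in bits: for a window b_1..b_L,

    W = sum_i  log2 f_i(b_i) - log2 P_bg(b_i | preceding bases)

with the background term conditioned on up to ``order`` preceding bases of
the window itself (truncated at the window start).  Column increments are
quantized to a 0.01-bit lattice, which makes the null score distribution
of a random L-mer computable exactly by dynamic programming over
(position, background context, lattice score) — for any background order —
so every reported match p-value P(W >= w) is exact rather than sampled.

The scanner reports at most one match per sequence by default ("no more
than one true binding site" assumption); every sequence also reports its
best score even when sub-threshold, which is what the enrichment curves
and the score-vs-peak-height correlation consume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genomic_io import GenomeSequence, GeneModel, Peak
from .synthetic_data import IUPAC, _revcomp

__all__ = [
    "GRID_BITS",
    "Pssm",
    "BackgroundModel",
    "MotifMatch",
    "SequenceScan",
    "MotifEnrichment",
    "train_background",
    "score_window",
    "match_pvalue",
    "score_threshold",
    "scan_sequences",
    "scan_peaks",
    "sample_random_promoters",
    "enrichment_curve",
    "intermotif_distances",
]

#: score lattice resolution, bits
GRID_BITS = 0.01

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_ENCODE_TABLE = np.full(256, 4, dtype=np.int8)
for _b, _c in _CODE.items():
    _ENCODE_TABLE[ord(_b)] = _c
    _ENCODE_TABLE[ord(_b.lower())] = _c


def _encode(seq: str) -> np.ndarray:
    return _ENCODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class BackgroundModel:
    """Order-m Markov sequence model with +1 pseudocount per context cell.

    ``conditionals[k]`` has shape (4**k, 4): P(base | k preceding bases),
    for every k from 0 to ``order`` — the truncated-context tables are what
    scores the first positions of a window.
    """

    def __init__(self, conditionals: list[np.ndarray], label: str = ""):
        self.order = len(conditionals) - 1
        self.conditionals = conditionals
        self.label = label
        for k, table in enumerate(conditionals):
            if table.shape != (4**k, 4):
                raise ValueError(f"order-{k} table has shape {table.shape}")
            if not np.allclose(table.sum(axis=1), 1.0):
                raise ValueError("conditional distributions must sum to 1")
            if (table <= 0).any():
                raise ValueError("all conditional probabilities must be positive")

    @classmethod
    def uniform(cls, order: int = 0) -> "BackgroundModel":
        return cls([np.full((4**k, 4), 0.25) for k in range(order + 1)], label="uniform")


def train_background(sequences, order: int = 2, label: str = "") -> BackgroundModel:
    """Estimate conditional base frequencies of every order up to ``order``."""
    if order < 0:
        raise ValueError("order must be >= 0")
    if isinstance(sequences, str):
        sequences = [sequences]
    total = sum(len(s) for s in sequences)
    if total < 4 ** (order + 1) * 10:
        raise ValueError(
            f"training set of {total} bp too small for order {order} "
            f"(need >= {4 ** (order + 1) * 10})"
        )
    encoded = [_encode(s) for s in sequences]
    conditionals = []
    for k in range(order + 1):
        counts = np.ones((4**k, 4))  # +1 pseudocount per cell
        for codes in encoded:
            if codes.size <= k:
                continue
            valid = codes < 4
            ctx = np.zeros(codes.size - k, dtype=np.int64)
            ok = valid[k:].copy()
            for j in range(1, k + 1):
                ctx += codes[k - j : codes.size - j].astype(np.int64) * 4 ** (j - 1)
                ok &= valid[k - j : codes.size - j]
            np.add.at(counts, (ctx[ok], codes[k:][ok]), 1)
        conditionals.append(counts / counts.sum(axis=1, keepdims=True))
    return BackgroundModel(conditionals, label=label)


class Pssm:
    """Position-specific scoring matrix over A,C,G,T with pseudocount applied."""

    def __init__(self, name: str, probs: np.ndarray, consensus: str = ""):
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 4:
            raise ValueError("PSSM must be (L, 4) with L >= 4")
        if not np.allclose(probs.sum(axis=1), 1.0):
            raise ValueError("PSSM columns must sum to 1")
        self.name = name
        self.probs = probs
        self.consensus = consensus or "".join("ACGT"[i] for i in probs.argmax(axis=1))
        self._cache: dict = {}

    def __len__(self) -> int:
        return self.probs.shape[0]

    @classmethod
    def from_counts(cls, name: str, counts: np.ndarray, pseudocount: float = 0.25) -> "Pssm":
        counts = np.asarray(counts, dtype=float) + pseudocount
        return cls(name, counts / counts.sum(axis=1, keepdims=True))

    @classmethod
    def from_consensus(cls, name: str, consensus: str, weight: float = 10.0,
                       pseudocount: float = 0.25) -> "Pssm":
        """Build a matrix from a (possibly IUPAC-degenerate) consensus:
        ``weight`` counts shared by the allowed bases per column."""
        counts = np.zeros((len(consensus), 4))
        for i, c in enumerate(consensus.upper()):
            allowed = IUPAC[c]
            for b in allowed:
                counts[i, _CODE[b]] = weight / len(allowed)
        pssm = cls.from_counts(name, counts, pseudocount)
        pssm.consensus = consensus.upper()
        return pssm


# ---------------------------------------------------------------------------
# lattice increments and the exact null distribution


def _increments(pssm: Pssm, background: BackgroundModel) -> list[np.ndarray]:
    """Integer lattice score increment per (position, context, base)."""
    key = ("inc", id(background))
    if key in pssm._cache:
        return pssm._cache[key]
    m = background.order
    out = []
    for i in range(len(pssm)):
        k = min(i, m)
        cond = background.conditionals[k]
        inc = np.rint((np.log2(pssm.probs[i]) - np.log2(cond)) / GRID_BITS).astype(np.int64)
        out.append(inc)  # shape (4**k, 4)
    pssm._cache[key] = out
    return out


def _null_distribution(pssm: Pssm, background: BackgroundModel):
    """Exact distribution of the lattice score of a background-drawn L-mer.

    Dynamic programme over (position, Markov context, lattice score);
    returns (minimum lattice score, survival function array) where
    ``sf[j] = P(score >= min + j)``.
    """
    key = ("null", id(background))
    if key in pssm._cache:
        return pssm._cache[key]
    inc = _increments(pssm, background)
    m = background.order
    lo = sum(int(a.min()) for a in inc)
    hi = sum(int(a.max()) for a in inc)
    width = hi - lo + 1

    # probs[ctx, j] = P(context, partial score = running_min + j)
    probs = np.zeros((1, width))
    probs[0, 0] = 1.0
    running_min = 0
    for i in range(len(pssm)):
        k = min(i, m)
        cond = background.conditionals[k]
        n_ctx_next = 4 ** min(i + 1, m)
        new = np.zeros((n_ctx_next, width))
        step_min = int(inc[i].min())
        for ctx in range(probs.shape[0]):
            row = probs[ctx]
            if not row.any():
                continue
            for b in range(4):
                p = cond[ctx, b]
                shift = int(inc[i][ctx, b]) - step_min
                nctx = (ctx * 4 + b) % n_ctx_next if m else 0
                new[nctx, shift : shift + width - shift] += row[: width - shift] * p
        probs = new
        running_min += step_min
    dist = probs.sum(axis=0)
    sf = np.cumsum(dist[::-1])[::-1]
    result = (running_min, sf)
    pssm._cache[key] = result
    return result


def score_window(window: str, pssm: Pssm, background: BackgroundModel) -> float:
    """Log-likelihood-ratio score of one window, in bits (lattice-quantized)."""
    codes = _encode(window)
    if codes.size != len(pssm):
        raise ValueError(f"window length {codes.size} != PSSM length {len(pssm)}")
    if (codes >= 4).any():
        raise ValueError("window contains N; score undefined")
    inc = _increments(pssm, background)
    m = background.order
    total = 0
    for i, b in enumerate(codes):
        k = min(i, m)
        ctx = 0
        for j in range(1, k + 1):
            ctx += int(codes[i - j]) * 4 ** (j - 1)
        total += int(inc[i][ctx, b])
    return total * GRID_BITS


def match_pvalue(score: float, pssm: Pssm, background: BackgroundModel) -> float:
    """Exact P(random background L-mer scores >= ``score``)."""
    lo, sf = _null_distribution(pssm, background)
    k = int(round(score / GRID_BITS))
    if k <= lo:
        return 1.0
    if k > lo + sf.size - 1:
        return 0.0
    return float(sf[k - lo])


def score_threshold(p_threshold: float, pssm: Pssm, background: BackgroundModel) -> float:
    """Smallest lattice score whose p-value is <= ``p_threshold``
    (+inf when no achievable score passes)."""
    lo, sf = _null_distribution(pssm, background)
    idx = np.flatnonzero(sf <= p_threshold)
    if idx.size == 0:
        return math.inf
    return (lo + int(idx[0])) * GRID_BITS


# ---------------------------------------------------------------------------
# scanning


@dataclass(frozen=True)
class MotifMatch:
    sequence_id: str
    center: int  # central coordinate of the matched window
    strand: str
    weight_score: float  # bits
    pvalue: float


@dataclass
class SequenceScan:
    """Best-hit record for one scanned sequence."""

    sequence_id: str
    best_score: float | None
    best_center: int | None
    best_strand: str | None
    best_pvalue: float | None
    matches: list[MotifMatch] = field(default_factory=list)

    @property
    def has_match(self) -> bool:
        return bool(self.matches)


def _window_scores(codes: np.ndarray, pssm: Pssm, background: BackgroundModel) -> np.ndarray:
    """Integer lattice score of every window on the given strand;
    windows containing N score minus infinity (returned as int64 min/2)."""
    inc = _increments(pssm, background)
    L, m = len(pssm), background.order
    n_win = codes.size - L + 1
    if n_win <= 0:
        return np.empty(0, dtype=np.int64)
    safe = np.where(codes < 4, codes, 0).astype(np.int64)
    total = np.zeros(n_win, dtype=np.int64)
    for i in range(L):
        b = safe[i : i + n_win]
        k = min(i, m)
        ctx = np.zeros(n_win, dtype=np.int64)
        for j in range(1, k + 1):
            ctx += safe[i - j : i - j + n_win] * 4 ** (j - 1)
        total += inc[i][ctx, b]
    has_n = np.convolve((codes >= 4).astype(int), np.ones(L, dtype=int), "valid") > 0
    total[has_n] = np.iinfo(np.int64).min // 2
    return total


def scan_sequences(
    sequences: dict[str, str],
    pssm: Pssm,
    background: BackgroundModel,
    p_threshold: float = 1e-5,
    best_only: bool = True,
    origins: dict[str, int] | None = None,
) -> list[SequenceScan]:
    """Scan both strands of each sequence.

    With ``best_only`` at most one match (the highest-scoring window; ties
    broken leftmost, plus strand first) is recorded per sequence, and only
    if its p-value passes the threshold; the best score is reported either
    way.  ``origins`` maps sequence id to the genomic coordinate of its
    first base so match centres come out in genome coordinates.
    """
    L = len(pssm)
    center_off = (L - 1) // 2
    thr_int = None
    lo, sf = _null_distribution(pssm, background)
    passing = np.flatnonzero(sf <= p_threshold)
    thr_int = (lo + int(passing[0])) if passing.size else None

    results = []
    for seq_id, seq in sequences.items():
        origin = (origins or {}).get(seq_id, 0)
        codes = _encode(seq)
        fwd = _window_scores(codes, pssm, background)
        rc = _window_scores(3 - codes[::-1] if codes.size else codes, pssm, background)
        # map revcomp window w' back to original start n - L - w'
        rev = rc[::-1] if rc.size else rc
        candidates = []  # (score, start, strand_rank, strand)
        if fwd.size:
            candidates.append((fwd, 0, "+"))
        if rev.size:
            candidates.append((rev, 1, "-"))
        if not candidates or all(c[0].size == 0 for c in candidates):
            results.append(SequenceScan(seq_id, None, None, None, None))
            continue

        def _pick(arrs):
            best = None
            for arr, rank, strand in arrs:
                w = int(arr.argmax())
                # leftmost occurrence of the max
                w = int(np.flatnonzero(arr == arr[w])[0])
                cand = (-int(arr[w]), w, rank, strand)
                if best is None or cand < best:
                    best = cand
            return best

        neg_score, start, _, strand = _pick(candidates)
        best_int = -neg_score
        min_int = np.iinfo(np.int64).min // 2
        if best_int <= min_int:  # every window contained N
            results.append(SequenceScan(seq_id, None, None, None, None))
            continue
        best_score = best_int * GRID_BITS
        best_p = match_pvalue(best_score, pssm, background)
        record = SequenceScan(
            sequence_id=seq_id,
            best_score=best_score,
            best_center=origin + start + center_off,
            best_strand=strand,
            best_pvalue=best_p,
        )
        if best_only:
            if thr_int is not None and best_int >= thr_int:
                record.matches.append(
                    MotifMatch(seq_id, record.best_center, strand, best_score, best_p)
                )
        else:
            for arr, _, st in candidates:
                if thr_int is None:
                    continue
                for w in np.flatnonzero(arr >= thr_int):
                    s = int(arr[w]) * GRID_BITS
                    record.matches.append(
                        MotifMatch(seq_id, origin + int(w) + center_off, st, s,
                                   match_pvalue(s, pssm, background))
                    )
        results.append(record)
    return results


def scan_peaks(
    peaks: list[Peak],
    genome: GenomeSequence,
    pssm: Pssm,
    background: BackgroundModel,
    half_width: int = 250,
    p_threshold: float = 1e-5,
    best_only: bool = True,
) -> list[SequenceScan]:
    """Scan summit +/- ``half_width`` windows of every peak.

    Peaks whose window crosses a chromosome edge are dropped.  Match
    centres are genomic coordinates.
    """
    sequences, origins = {}, {}
    for p in peaks:
        start, end = p.summit - half_width, p.summit + half_width + 1
        if start < 0 or end > genome.lengths[p.chrom]:
            continue
        sequences[p.peak_id] = genome.fetch(p.chrom, start, end)
        origins[p.peak_id] = start
    return scan_sequences(sequences, pssm, background, p_threshold, best_only, origins)


def sample_random_promoters(
    genes: list[GeneModel],
    genome: GenomeSequence,
    n: int,
    length: int,
    rng: np.random.Generator,
    exclude_gene_ids: set[str] | None = None,
) -> dict[str, str]:
    """Sample ``n`` promoter windows of ``length`` bp upstream of TSSs.

    Used as the matched random control for enrichment curves; genes whose
    promoters carry peaks can be excluded so the control is binding-free.
    """
    pool = [g for g in genes if not exclude_gene_ids or g.gene_id not in exclude_gene_ids]
    out: dict[str, str] = {}
    order = rng.permutation(len(pool))
    for idx in order:
        if len(out) >= n:
            break
        g = pool[idx]
        if g.strand == "+":
            start, end = g.tss - length, g.tss
        else:
            start, end = g.tss + 1, g.tss + 1 + length
        if start < 0 or end > genome.lengths[g.chrom]:
            continue
        out[f"rand_{g.gene_id}"] = genome.fetch(g.chrom, start, end)
    if len(out) < n:
        raise ValueError(f"could only sample {len(out)} of {n} random promoters")
    return out


# ---------------------------------------------------------------------------
# enrichment and spacing


@dataclass
class MotifEnrichment:
    thresholds: np.ndarray  # bits
    freq_peaks: np.ndarray  # fraction of peak sequences with best score >= t
    freq_random: np.ndarray
    r: float  # match-frequency ratio at the p-value threshold
    n_peak_matches: int
    n_random_matches: int
    pearson_r_vs_height: float | None
    ttest_p: float  # unpaired t-test between the two frequency profiles


def enrichment_curve(
    peak_scans: list[SequenceScan],
    random_scans: list[SequenceScan],
    peak_heights: dict[str, float] | None = None,
    grid_step: float = 0.5,
) -> MotifEnrichment:
    """Best-score frequency profiles in peaks vs random promoters.

    ``r`` is the ratio of the fraction of sequences carrying a
    threshold-passing match (peaks over random); +inf flags a zero random
    frequency.  When peak heights are given, the Pearson correlation of
    best score vs height is reported.
    """
    if len(peak_scans) != len(random_scans):
        raise ValueError("peak and random sequence counts must match")

    def _scores(scans):
        return np.array(
            [s.best_score if s.best_score is not None else -math.inf for s in scans]
        )

    sp, sr = _scores(peak_scans), _scores(random_scans)
    top = max(sp.max(initial=0.0), sr.max(initial=0.0))
    thresholds = np.arange(0.0, top + grid_step, grid_step)
    freq_peaks = np.array([(sp >= t).mean() for t in thresholds])
    freq_random = np.array([(sr >= t).mean() for t in thresholds])

    n_pk = sum(1 for s in peak_scans if s.has_match)
    n_rd = sum(1 for s in random_scans if s.has_match)
    f_pk, f_rd = n_pk / len(peak_scans), n_rd / len(random_scans)
    r = math.inf if f_rd == 0 else f_pk / f_rd

    pearson = None
    if peak_heights is not None:
        pairs = [
            (s.best_score, peak_heights[s.sequence_id])
            for s in peak_scans
            if s.best_score is not None and s.sequence_id in peak_heights
        ]
        if len(pairs) >= 3:
            x, y = zip(*pairs)
            if np.std(x) > 0 and np.std(y) > 0:
                pearson = float(stats.pearsonr(x, y)[0])
    ttest_p = float(stats.ttest_ind(freq_peaks, freq_random)[1])
    return MotifEnrichment(
        thresholds=thresholds,
        freq_peaks=freq_peaks,
        freq_random=freq_random,
        r=r,
        n_peak_matches=n_pk,
        n_random_matches=n_rd,
        pearson_r_vs_height=pearson,
        ttest_p=ttest_p,
    )


def intermotif_distances(
    ref_positions,
    other_matches: list[MotifMatch],
    promoter_strands: dict[str, str],
    bin_width: int = 10,
):
    """Strand-aware distances from a reference motif (or summit) to another.

    ``ref_positions`` is either a list of matches or a dict mapping
    sequence id to a reference coordinate (e.g. the peak summit).  For each
    sequence carrying both, d = (centre_other - centre_ref) * strand sign
    of the promoter.  Returns (distances, (bin_centres, counts), mode).
    """
    if isinstance(ref_positions, dict):
        ref = dict(ref_positions)
    else:
        ref = {m.sequence_id: m.center for m in ref_positions}
    other: dict[str, int] = {}
    for m in other_matches:
        other.setdefault(m.sequence_id, m.center)

    distances = []
    for seq_id, c_ref in ref.items():
        if seq_id not in other:
            continue
        sign = -1 if promoter_strands.get(seq_id, "+") == "-" else 1
        distances.append((other[seq_id] - c_ref) * sign)
    distances = np.array(distances, dtype=int)
    if distances.size == 0:
        return distances, (np.empty(0), np.empty(0, dtype=int)), None
    half = bin_width / 2
    lo = math.floor((distances.min() + half) / bin_width) * bin_width - half
    hi = math.ceil((distances.max() + half) / bin_width) * bin_width + half
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(distances, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    mode = float(centers[int(np.argmax(counts))])
    return distances, (centers, counts), mode
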