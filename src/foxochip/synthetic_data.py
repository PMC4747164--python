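"""Synthetic genome, ChIP-seq and RNA-seq generator with planted ground truth.

Emulates the three-strain design of a DAF-16/FOXO binding study — wild type,
the low-insulin-signalling *daf-2* mutant, and the *daf-16;daf-2* double
mutant in which the factor is absent.  A toy genome is tiled with genes; a
configurable fraction is "bound": a consensus motif is written into the
promoter at a planted summit distance upstream of the TSS, ChIP fragments
pile up around the planted summit over a uniform background, and expression
counts couple activation to promoter-proximal binding (activated genes are
drawn from the bound set, repressed genes from the unbound set, and neither
responds in the *daf-16* null).  Everything is deterministic under the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .genomic_io import GenomeSequence, GeneModel, Peak, ReadAlignment
from .peak_annotation import band_for_distance

__all__ = [
    "CONDITIONS",
    "SimulationConfig",
    "GeneTruth",
    "GroundTruth",
    "simulate_genome",
    "simulate_chip",
    "simulate_expression",
]

#: the three strains: wild type, low-IIS mutant, and the factor-null double mutant
CONDITIONS = ("WT", "daf-2", "daf-16;daf-2")
#: the condition in which the ChIP target is absent (background-only ChIP,
#: no transcriptional response)
NULL_CONDITION = "daf-16;daf-2"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: IUPAC degenerate DNA codes (subset used for consensus strings)
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults define the study conditions."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 800_000
    n_genes: int = 300
    gc_content: float = 0.36
    motif_consensus: str = "SYGGTAAACAASR"
    comotif_consensus: str = "TGATAAGACGTA"
    comotif_offset: int = 40
    comotif_fraction: float = 0.6
    motif_fraction: float = 1.0
    fraction_bound_genes: float = 0.3
    fraction_activated: float = 0.7
    fraction_repressed: float = 0.15
    planted_summit_distance_bands: tuple[int, ...] = (100, 250, 400, 700, 1200, 2000)
    fragment_length: int = 175
    read_length: int = 36
    chip_enrichment: float = 10.0
    reads_per_sample: int = 400_000
    nb_mean: float = 200.0
    nb_dispersion: float = 0.02
    activation_fold: float = 4.0
    distance_decay: bool = False
    n_replicates: int = 3
    #: reads mapped to transcripts outside the simulated gene panel; keeps
    #: library totals dominated by the unchanged transcriptome, as in real
    #: RNA-seq, so fold changes are not compressed by composition shifts
    library_background_reads: int = 1_000_000

    def __post_init__(self) -> None:
        for name in ("fraction_bound_genes", "fraction_activated", "fraction_repressed",
                     "comotif_fraction", "motif_fraction", "gc_content"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.fragment_length <= self.read_length:
            raise ValueError("fragment_length must exceed read_length")
        if self.activation_fold < 1:
            raise ValueError("activation_fold must be >= 1")
        if self.chip_enrichment < 1:
            raise ValueError("chip_enrichment must be >= 1")


@dataclass
class GeneTruth:
    """Planted state of one gene."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    exon_length: int
    bound: bool = False
    summit: int | None = None
    distance: int | None = None  # planted upstream distance, bp
    band: str | None = None
    expr_class: str = "unchanged"  # activated | repressed | unchanged
    motifs: list = field(default_factory=list)  # (name, center, strand) tuples
    has_comotif: bool = False


@dataclass
class GroundTruth:
    """Per-gene planted state plus the genome shape, enough to score every stage."""

    genes: dict[str, GeneTruth]
    chrom_lengths: dict[str, int]

    @property
    def bound_genes(self) -> list[str]:
        return [g for g, t in self.genes.items() if t.bound]

    def genes_of_class(self, expr_class: str) -> list[str]:
        return [g for g, t in self.genes.items() if t.expr_class == expr_class]

    @property
    def n_planted_motifs(self) -> int:
        return sum(1 for t in self.genes.values() for m in t.motifs if m[0] == "primary")

    def to_json(self, path: str) -> None:
        payload = {
            "chrom_lengths": self.chrom_lengths,
            "genes": {g: asdict(t) for g, t in self.genes.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        genes = {
            g: GeneTruth(**{**d, "motifs": [tuple(m) for m in d["motifs"]]})
            for g, d in payload["genes"].items()
        }
        return cls(genes=genes, chrom_lengths=payload["chrom_lengths"])


# ---------------------------------------------------------------------------
# genome + annotation + motif planting

_GENE_SPAN = 1500  # two exons of 600 bp separated by a 300-bp intron


def simulate_genome(config: SimulationConfig) -> tuple[GenomeSequence, list[GeneModel], GroundTruth]:
    """Build the toy genome: i.i.d. background bases, tiled genes, planted motifs.

    Genes alternate strand and are tiled with >=5 kb start-to-start spacing so
    each promoter window belongs unambiguously to one TSS.  For each bound
    gene the primary motif consensus is written centred on the planted summit
    (strand chosen uniformly); a configured fraction additionally receives
    the co-motif at ``comotif_offset`` bp from the primary motif's centre,
    measured in the promoter's transcription orientation.
    """
    rng = np.random.default_rng([config.seed, 1])

    per_chrom = -(-config.n_genes // config.n_chroms)  # ceil
    slot = config.chrom_length // per_chrom
    # TSS sits 2700 bp into each slot: room for a 2.5-kb promoter upstream
    # on either strand and the 1.5-kb gene body downstream
    if slot < 5300:
        raise ValueError(
            f"{config.n_genes} genes do not fit in {config.n_chroms}x{config.chrom_length} bp "
            "at >=5 kb spacing"
        )

    p = np.array([(1 - config.gc_content) / 2, config.gc_content / 2,
                  config.gc_content / 2, (1 - config.gc_content) / 2])
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    chrom_arrays: dict[str, np.ndarray] = {}
    for c in range(config.n_chroms):
        chrom_arrays[f"chr{c + 1}"] = alphabet[rng.choice(4, size=config.chrom_length, p=p)]

    genes: list[GeneModel] = []
    truth_genes: dict[str, GeneTruth] = {}
    gi = 0
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        for s in range(per_chrom):
            if gi >= config.n_genes:
                break
            strand = "+" if gi % 2 == 0 else "-"
            slot_start = s * slot
            tss = slot_start + 2700
            if strand == "+":
                exons = ((tss, tss + 600), (tss + 900, tss + _GENE_SPAN))
            else:
                exons = ((tss - _GENE_SPAN + 1, tss - 899), (tss - 599, tss + 1))
            gid = f"g{gi:04d}"
            genes.append(GeneModel(gid, chrom, strand, tss, exons))
            truth_genes[gid] = GeneTruth(
                gene_id=gid, chrom=chrom, strand=strand, tss=tss,
                exon_length=sum(e - s0 for s0, e in exons),
            )
            gi += 1

    n_bound = round(config.n_genes * config.fraction_bound_genes)
    bound_ids = sorted(rng.choice(config.n_genes, size=n_bound, replace=False))
    bands = config.planted_summit_distance_bands
    for k, idx in enumerate(bound_ids):
        g = genes[idx]
        t = truth_genes[g.gene_id]
        d = int(bands[k % len(bands)])
        sign = 1 if g.strand == "+" else -1
        summit = g.tss - d * sign
        t.bound = True
        t.summit = summit
        t.distance = d
        t.band = band_for_distance(-d)
        if rng.random() < config.motif_fraction:
            _plant(chrom_arrays[g.chrom], config.motif_consensus, summit, rng, t, "primary")
            if rng.random() < config.comotif_fraction:
                primary_center = t.motifs[-1][1]
                co_center = primary_center + config.comotif_offset * sign
                _plant(chrom_arrays[g.chrom], config.comotif_consensus, co_center, rng, t,
                       "comotif")
                t.has_comotif = True

    # expression classes: activation is coupled to binding, repression is not
    n_act = round(n_bound * config.fraction_activated)
    act_ids = rng.choice(len(bound_ids), size=n_act, replace=False)
    for j in act_ids:
        truth_genes[genes[bound_ids[j]].gene_id].expr_class = "activated"
    unbound = [i for i in range(config.n_genes) if i not in set(bound_ids)]
    n_rep = round(len(unbound) * config.fraction_repressed)
    rep_ids = rng.choice(len(unbound), size=n_rep, replace=False)
    for j in rep_ids:
        truth_genes[genes[unbound[j]].gene_id].expr_class = "repressed"

    genome = GenomeSequence(
        {name: arr.tobytes().decode("ascii") for name, arr in chrom_arrays.items()}
    )
    truth = GroundTruth(genes=truth_genes, chrom_lengths=genome.lengths)
    return genome, genes, truth


def _plant(chrom_arr: np.ndarray, consensus: str, center: int, rng, truth: GeneTruth,
           name: str) -> None:
    """Write a realization of the (possibly IUPAC-degenerate) ``consensus``,
    strand chosen uniformly, centred at ``center``."""
    L = len(consensus)
    start = center - (L - 1) // 2
    word = "".join(
        IUPAC[c][rng.integers(len(IUPAC[c]))] for c in consensus.upper()
    )
    strand = "+" if rng.random() < 0.5 else "-"
    seq = word if strand == "+" else _revcomp(word)
    chrom_arr[start : start + L] = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    truth.motifs.append((name, start + (L - 1) // 2, strand))


# ---------------------------------------------------------------------------
# ChIP reads and peaks


def simulate_chip(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[dict[str, list[ReadAlignment]], dict[str, list[ReadAlignment]], dict[str, list[Peak]]]:
    """Simulate single-end ChIP and input reads per condition, plus called peaks.

    Background fragment midpoints are uniform over the genome at
    ``reads_per_sample`` fragments per sample.  Around each planted summit,
    enriched fragment midpoints are drawn Normal(summit, fragment_length/4);
    their number is chosen so the midpoint density at the summit is
    ``chip_enrichment``-fold the background density.  In the factor-null
    condition the enrichment multiplier is forced to 1 (background only).
    Each fragment is reported as one read from a uniformly chosen end.
    Returns (chip reads, input reads, peaks) keyed by condition; peaks carry
    the planted summit and ``height = chip_enrichment``.
    """
    chip: dict[str, list[ReadAlignment]] = {}
    inputs: dict[str, list[ReadAlignment]] = {}
    peaks: dict[str, list[Peak]] = {}
    genome_len = sum(truth.chrom_lengths.values())
    sd = config.fragment_length / 4.0
    lam = config.reads_per_sample / genome_len  # background midpoints per bp
    n_enr_mean = (config.chip_enrichment - 1.0) * lam * sd * np.sqrt(2 * np.pi)

    summits = [(t.chrom, t.summit) for t in truth.genes.values() if t.bound]

    for ci, cond in enumerate(CONDITIONS):
        rng = np.random.default_rng([config.seed, 2, ci])
        enriched = cond != NULL_CONDITION
        reads = _background_reads(config, truth, rng, cond)
        if enriched:
            for chrom, summit in summits:
                n = rng.poisson(n_enr_mean)
                mids = rng.normal(summit, sd, size=n)
                reads.extend(
                    _fragments_to_reads(mids, chrom, config, truth.chrom_lengths[chrom], rng, cond)
                )
        chip[cond] = reads
        inputs[cond] = _background_reads(config, truth, rng, f"input_{cond}")
        if enriched:
            peaks[cond] = [
                Peak(
                    peak_id=f"{cond}_p{i}",
                    chrom=chrom,
                    start=summit - 200,
                    end=summit + 201,
                    summit=summit,
                    height=config.chip_enrichment,
                    pvalue=1e-10,
                    condition=cond,
                )
                for i, (chrom, summit) in enumerate(summits)
            ]
        else:
            peaks[cond] = []
    return chip, inputs, peaks


def _background_reads(config, truth, rng, sample) -> list[ReadAlignment]:
    genome_len = sum(truth.chrom_lengths.values())
    reads = []
    for chrom, length in truth.chrom_lengths.items():
        n = round(config.reads_per_sample * length / genome_len)
        mids = rng.uniform(0, length, size=n)
        reads.extend(_fragments_to_reads(mids, chrom, config, length, rng, sample))
    return reads


def _fragments_to_reads(mids, chrom, config, chrom_len, rng, sample) -> list[ReadAlignment]:
    """One single-end read per fragment, sequenced from a uniformly chosen end."""
    mids = np.asarray(mids)
    half = config.fragment_length // 2
    from_plus = rng.random(size=mids.size) < 0.5
    starts = np.where(
        from_plus,
        np.rint(mids).astype(np.int64) - half,
        np.rint(mids).astype(np.int64) + half - config.read_length,
    )
    ends = starts + config.read_length
    keep = (starts >= 0) & (ends <= chrom_len)
    return [
        ReadAlignment(chrom, int(s), int(e), "+" if fp else "-", sample)
        for s, e, fp in zip(starts[keep], ends[keep], from_plus[keep])
    ]


# ---------------------------------------------------------------------------
# expression counts


def simulate_expression(config: SimulationConfig, truth: GroundTruth):
    """Negative-binomial count table, genes x (condition, replicate).

    Per-gene baseline means are lognormal around ``nb_mean`` (drawn once,
    deterministic under seed).  Activated genes are scaled by
    ``activation_fold`` in the daf-2 condition, repressed genes by its
    reciprocal; in the factor-null condition every effect is 1.  With
    ``distance_decay`` the activation effect shrinks exponentially with the
    planted summit distance (length scale 1 kb).

    Returns a pandas DataFrame (rows: genes; columns: ``<cond>_r<k>``), a
    dict mapping column name -> condition, and a per-sample Series of total
    mapped reads (panel counts plus the rest-of-transcriptome background).
    """
    import pandas as pd

    rng = np.random.default_rng([config.seed, 3])
    gene_ids = list(truth.genes)
    n = len(gene_ids)
    baseline = rng.lognormal(mean=np.log(config.nb_mean), sigma=0.5, size=n)

    effects = np.ones((n, len(CONDITIONS)))
    di = CONDITIONS.index("daf-2")
    for i, gid in enumerate(gene_ids):
        t = truth.genes[gid]
        fold = config.activation_fold
        if config.distance_decay and t.distance is not None:
            fold = 1.0 + (config.activation_fold - 1.0) * np.exp(-t.distance / 1000.0)
        if t.expr_class == "activated":
            effects[i, di] = fold
        elif t.expr_class == "repressed":
            effects[i, di] = 1.0 / config.activation_fold

    alpha = config.nb_dispersion
    columns = {}
    condition_of = {}
    for ci, cond in enumerate(CONDITIONS):
        for r in range(1, config.n_replicates + 1):
            mu = baseline * effects[:, ci]
            if alpha > 0:
                size = 1.0 / alpha
                counts = rng.negative_binomial(size, size / (size + mu))
            else:
                counts = rng.poisson(mu)
            col = f"{cond}_r{r}"
            columns[col] = counts
            condition_of[col] = cond
    table = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    totals = table.sum(axis=0) + config.library_background_reads
    return table, condition_of, totals
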