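"""Synthetic laminar atlas generator.

Emulates the statistical structure the pipeline assumes so every stage can be
exercised without external data: log-normally noised FPKM profiles with a
planted fold-enrichment in the samples mapped to each gene's true layer,
CI widths proportional to expression, label noise in the curations, planted
term sets of configurable purity, two-isoform switch genes with mirrored
profiles, and a toy genome with coding genes and intergenic multiexonic
noncoding transcripts.

The sample -> layer correspondence is an explicit table. Dissections overlap
layers, so when a sample maps to more than one layer a gene of that layer is
elevated with bleed weight 0.5 (the enrichment acts as ``fold ** weight``);
a sample mapped to a single layer carries full weight 1. Layer-1 genes are
generated but never curated, since no reliable layer-1 classifier can be
trained from curated markers.
"""

from __future__ import annotations

import dataclasses
import os
from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np

from .enrichment import TermDB, write_termdb_tsv
from .expression import (
    DEFAULT_SAMPLE_LAYER_MAP,
    LAYERS,
    NO_ENRICHMENT,
    CurationLabel,
    QuantRecord,
    SampleSet,
    write_curation_tsv,
    write_quant_tsv,
)
from .lincrna import TranscriptModel, write_gtf

UNPATTERNED = "unpatterned"
_SLUG = {"L2/3": "L23", "L4": "L4", "L5": "L5", "L6": "L6", "L6b": "L6b",
         UNPATTERNED: "unp", "L1": "L1"}


@dataclass(frozen=True)
class GenomeConfig:
    """Toy genome layout for the lincRNA stage."""

    chrom_lengths: tuple[tuple[str, int], ...] = (("chr1", 2_000_000), ("chr2", 2_000_000))
    n_coding_genes: int = 80
    n_lincrna: int = 40


@dataclass(frozen=True)
class AtlasConfig:
    """Study conditions for one synthetic atlas."""

    n_genes_per_class: int = 200
    n_l1_genes: int = 50
    enrichment_fold: float = 4.0
    base_fpkm_log_mean: float = 1.0
    base_fpkm_log_sd: float = 1.0
    noise_sd: float = 0.3
    ci_width_frac: float = 0.1
    label_noise_rate: float = 0.1
    n_switch_genes: int = 20
    term_purity: float = 0.8
    planted_term_size: int = 40
    n_null_terms: int = 20
    null_term_size: int = 30
    bleed_weight: float = 0.5
    sample_layer_map: tuple[tuple[str, tuple[str, ...]], ...] = tuple(
        (s, tuple(sorted(ls))) for s, ls in DEFAULT_SAMPLE_LAYER_MAP.items())
    genome: GenomeConfig = GenomeConfig()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes_per_class < 0 or self.n_l1_genes < 0 or self.n_switch_genes < 0:
            raise ValueError("counts must be >= 0")
        if self.enrichment_fold <= 1:
            raise ValueError("enrichment_fold must exceed 1")
        if not (0.0 <= self.label_noise_rate < 1.0):
            raise ValueError("label_noise_rate must be in [0, 1)")
        if self.ci_width_frac < 0:
            raise ValueError("ci_width_frac must be >= 0")
        if self.n_genes_per_class == 0 and (self.n_null_terms or self.planted_term_size):
            raise ValueError("planted terms reference empty classes")

    @property
    def samples(self) -> SampleSet:
        return SampleSet(names=tuple(s for s, _ in self.sample_layer_map),
                         layer_map={s: frozenset(ls) for s, ls in self.sample_layer_map})

    def enrichment_weights(self, layer: str) -> np.ndarray:
        """Per-sample exponent on the enrichment fold for a gene of ``layer``."""
        w = np.zeros(len(self.sample_layer_map))
        for i, (_s, layers) in enumerate(self.sample_layer_map):
            if layer in layers:
                w[i] = 1.0 if len(layers) == 1 else self.bleed_weight
        return w


@dataclass
class SyntheticAtlas:
    """A complete generated data set with its ground truth."""

    config: AtlasConfig
    samples: SampleSet
    quant_table: list[QuantRecord]
    truth: dict[str, str]
    curations: list[CurationLabel]
    transcripts: list[TranscriptModel]
    term_db: TermDB

    def __post_init__(self) -> None:
        ids = {r.feature_id for r in self.quant_table}
        for c in self.curations:
            if c.gene_id not in ids:
                raise ValueError(f"curated gene {c.gene_id} missing from quant table")
        missing = ids - set(self.truth)
        if missing:
            raise ValueError(f"truth does not cover {sorted(missing)[:3]}...")


def _gene_record(rng: np.random.Generator, cfg: AtlasConfig, feature_id: str,
                 weights: np.ndarray, kind: str = "gene",
                 gene_id: str | None = None) -> QuantRecord:
    base = float(np.exp(rng.normal(cfg.base_fpkm_log_mean, cfg.base_fpkm_log_sd)))
    mean = base * cfg.enrichment_fold ** weights
    # noise draws are unconditional so the RNG stream (and hence the baseline
    # expression of every later gene) is identical across noise settings
    noise = np.exp(rng.normal(0.0, cfg.noise_sd, size=weights.size))
    fpkm = mean * noise
    # CI half-width scales with the gene's expression level (mean FPKM across
    # samples), keeping quantification uncertainty comparable across a profile
    half = cfg.ci_width_frac * float(np.mean(fpkm))
    return QuantRecord(
        feature_id=feature_id, feature_kind=kind, gene_id=gene_id or feature_id,
        fpkm=fpkm, ci_lo=np.maximum(fpkm - half, 0.0), ci_hi=fpkm + half)


def _noisy_label(rng: np.random.Generator, true_class: str, rate: float) -> str:
    classes = list(LAYERS) + [UNPATTERNED]
    if rate > 0 and rng.random() < rate:
        wrong = [c for c in classes if c != true_class]
        return wrong[int(rng.integers(len(wrong)))]
    return true_class


def _curation(gene_id: str, cls: str) -> CurationLabel:
    if cls == UNPATTERNED:
        return CurationLabel(gene_id=gene_id, no_enrichment=True)
    return CurationLabel(gene_id=gene_id, enriched_layers=frozenset({cls}))


def generate_atlas(config: AtlasConfig) -> SyntheticAtlas:
    """Generate a full atlas: expression, truth, curations, genome, terms.

    Deterministic given ``config.seed``; the same config yields byte-identical
    written outputs.
    """
    rng = np.random.default_rng(config.seed)
    samples = config.samples
    classes = list(LAYERS) + [UNPATTERNED]

    quant: list[QuantRecord] = []
    truth: dict[str, str] = {}
    curations: list[CurationLabel] = []
    genes_by_class: dict[str, list[str]] = {c: [] for c in classes}

    for cls in classes + ["L1"]:
        n = config.n_l1_genes if cls == "L1" else config.n_genes_per_class
        weights = (np.zeros(len(samples)) if cls == UNPATTERNED
                   else config.enrichment_weights(cls))
        for i in range(n):
            gid = f"g_{_SLUG[cls]}_{i:04d}"
            quant.append(_gene_record(rng, config, gid, weights))
            truth[gid] = cls
            if cls != "L1":
                genes_by_class[cls].append(gid)
                curations.append(_curation(gid, _noisy_label(
                    rng, cls, config.label_noise_rate)))

    term_db = _planted_terms(rng, config, genes_by_class)
    transcripts, linc_records, linc_truth = _toy_genome(rng, config, samples)
    quant.extend(linc_records)
    truth.update(linc_truth)

    return SyntheticAtlas(config=config, samples=samples, quant_table=quant,
                          truth=truth, curations=curations,
                          transcripts=transcripts, term_db=term_db)


def _planted_terms(rng: np.random.Generator, cfg: AtlasConfig,
                   genes_by_class: dict[str, list[str]]) -> TermDB:
    """One term per layer concentrated in that layer's genes at the configured
    purity, plus uniform null terms."""
    all_genes = [g for genes in genes_by_class.values() for g in genes]
    terms: dict[str, frozenset[str]] = {}
    for layer in LAYERS:
        pool = genes_by_class[layer]
        size = min(cfg.planted_term_size, len(pool))
        n_pure = int(round(cfg.term_purity * size))
        members = list(rng.choice(pool, size=n_pure, replace=False))
        others = [g for g in all_genes if g not in set(members)]
        if size - n_pure > 0:
            members += list(rng.choice(others, size=size - n_pure, replace=False))
        terms[f"term_{_SLUG[layer]}"] = frozenset(members)
    for k in range(cfg.n_null_terms):
        size = min(cfg.null_term_size, len(all_genes))
        terms[f"null_{k:03d}"] = frozenset(rng.choice(all_genes, size=size, replace=False))
    return TermDB(name="synthetic_terms", conditional=False, terms=terms)


def _toy_genome(rng: np.random.Generator, cfg: AtlasConfig, samples: SampleSet):
    """Lay coding genes along chromosomes with intergenic multiexonic
    noncoding transcripts placed in the gaps between them."""
    classes = list(LAYERS) + [UNPATTERNED]
    coding_ids = []
    for i in range(cfg.genome.n_coding_genes):
        cls = classes[i % len(classes)]
        idx = i // len(classes)
        if idx < cfg.n_genes_per_class:
            coding_ids.append(f"g_{_SLUG[cls]}_{idx:04d}")
    transcripts: list[TranscriptModel] = []
    linc_records: list[QuantRecord] = []
    linc_truth: dict[str, str] = {}
    chroms = list(cfg.genome.chrom_lengths)
    gene_spacing = 20_000
    pos_by_chrom = {c: 5_000 for c, _ in chroms}
    linc_slots: list[tuple[str, int]] = []
    for i, gid in enumerate(coding_ids):
        chrom, length = chroms[i % len(chroms)]
        start = pos_by_chrom[chrom]
        if start + 3_000 > length:
            continue
        exons = [(start, start + 200), (start + 700, start + 900),
                 (start + 1_400, start + 1_600)]
        transcripts.append(TranscriptModel(
            transcript_id=f"tx_{gid}", gene_id=gid, chrom=chrom,
            strand="+" if i % 2 == 0 else "-", exons=exons,
            biotype="protein_coding", coding_label="coding"))
        linc_slots.append((chrom, start + 1_600 + gene_spacing // 2))
        pos_by_chrom[chrom] = start + 1_600 + gene_spacing
    for k in range(min(cfg.genome.n_lincrna, len(linc_slots))):
        chrom, start = linc_slots[k]
        lid = f"linc_{k:04d}"
        tid = f"{lid}_t1"
        exons = [(start, start + 300), (start + 700, start + 1_000)]
        transcripts.append(TranscriptModel(
            transcript_id=tid, gene_id=lid, chrom=chrom,
            strand="+" if k % 2 == 0 else "-", exons=exons,
            biotype="noncoding", coding_label="noncoding"))
        cls = classes[int(rng.integers(len(classes)))]
        weights = (np.zeros(len(samples)) if cls == UNPATTERNED
                   else cfg.enrichment_weights(cls))
        linc_records.append(_gene_record(rng, cfg, tid, weights,
                                         kind="transcript", gene_id=lid))
        linc_truth[tid] = cls
    return transcripts, linc_records, linc_truth


def generate_switch_fixture(config: AtlasConfig) -> SyntheticAtlas:
    """Atlas augmented with two-isoform genes whose transcript FPKM profiles
    are mirror images across the sample axis (upper-layer-like vs
    deep-layer-like), with non-overlapping CIs between the end samples when
    the CI width fraction is small enough. Gene FPKM is the transcript sum."""
    if config.n_switch_genes < 1:
        raise ValueError("n_switch_genes must be >= 1")
    atlas = generate_atlas(config)
    rng = np.random.default_rng(config.seed + 1_000_003)
    n_s = len(atlas.samples)
    gradient = np.linspace(1.0, 0.0, n_s)
    for k in range(config.n_switch_genes):
        gid = f"sw_{k:04d}"
        base = float(np.exp(rng.normal(config.base_fpkm_log_mean,
                                       config.base_fpkm_log_sd)))
        p1 = base * config.enrichment_fold ** gradient
        p2 = p1[::-1].copy()
        for tid, prof in ((f"{gid}_t1", p1), (f"{gid}_t2", p2)):
            half = config.ci_width_frac * float(np.mean(prof))
            atlas.quant_table.append(QuantRecord(
                feature_id=tid, feature_kind="transcript", gene_id=gid,
                fpkm=prof, ci_lo=np.maximum(prof - half, 0.0), ci_hi=prof + half))
            atlas.truth[tid] = "switch"
        gsum = p1 + p2
        half = config.ci_width_frac * float(np.mean(gsum))
        atlas.quant_table.append(QuantRecord(
            feature_id=gid, feature_kind="gene", gene_id=gid,
            fpkm=gsum, ci_lo=np.maximum(gsum - half, 0.0), ci_hi=gsum + half))
        atlas.truth[gid] = "switch"
    return atlas


def write_atlas(atlas: SyntheticAtlas, outdir) -> None:
    """Write the standard pipeline inputs: quantification TSV, curation TSV,
    transcript GTF, term-DB TSV and chromosome sizes TSV."""
    os.makedirs(outdir, exist_ok=True)
    meta = [f"seed={atlas.config.seed}"]
    write_quant_tsv(os.path.join(outdir, "quant.tsv"), atlas.quant_table,
                    atlas.samples, header_comments=meta)
    write_curation_tsv(os.path.join(outdir, "curations.tsv"), atlas.curations,
                       header_comments=meta)
    write_gtf(os.path.join(outdir, "transcripts.gtf"), atlas.transcripts)
    write_termdb_tsv(os.path.join(outdir, "terms.tsv"), atlas.term_db)
    with open(os.path.join(outdir, "chrom_sizes.tsv"), "w", encoding="utf-8") as fh:
        for chrom, length in atlas.config.genome.chrom_lengths:
            fh.write(f"{chrom}\t{length}\n")
    with open(os.path.join(outdir, "truth.tsv"), "w", encoding="utf-8") as fh:
        fh.write("feature_id\ttrue_class\n")
        for fid in sorted(atlas.truth):
            fh.write(f"{fid}\t{atlas.truth[fid]}\n")
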