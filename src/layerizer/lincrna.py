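"""Long intergenic noncoding RNA identification and positional statistics.

Candidate lincRNAs are multiexonic transcripts, longer than 200 exonic bases,
externally labelled noncoding, whose exons avoid the expanded territory of
every protein-coding gene (a gene's territory is its exon span together with
the spans of transcripts sharing at least one exonic base with it). Candidates
are clustered into loci: connected components of transcripts whose genomic
spans (first exon start to last exon end, so intronic or exonic bases alike)
share at least one base on either strand.

Positional tests: adjacency of patterned coding genes to lincRNA loci (label
permutation), neighbour expression correlation (rank-sum over per-pair
absolute Spearman correlations), and interval-overlap enrichment against a
shuffled-placement null.

Coordinates are 0-based half-open internally; GTF I/O converts to and from the
1-based inclusive convention.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class TranscriptModel:
    """Exon-level transcript model; exons are 0-based half-open, sorted."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    biotype: str = "unknown"  # protein_coding | noncoding | unknown
    coding_label: str = "unset"  # coding | noncoding | unset

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: at least one exon required")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        prev_end = -1
        for a, b in self.exons:
            if a < 0 or b <= a:
                raise ValueError(f"{self.transcript_id}: bad exon ({a}, {b})")
            if a < prev_end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
            prev_end = b

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def exonic_length(self) -> int:
        return sum(b - a for a, b in self.exons)


@dataclass
class Locus:
    locus_id: str
    member_ids: tuple[str, ...]
    chrom: str
    span: tuple[int, int]


# ---------------------------------------------------------------------------
# GTF I/O (1-based inclusive on disk)
# ---------------------------------------------------------------------------

def write_gtf(path, transcripts: Iterable[TranscriptModel]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in transcripts:
            for a, b in t.exons:
                attrs = (f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                         f'gene_biotype "{t.biotype}";')
                fh.write("\t".join([t.chrom, "layerizer", "exon", str(a + 1), str(b),
                                    ".", t.strand, ".", attrs]) + "\n")


def read_gtf(path) -> list[TranscriptModel]:
    """Read exon features from a GTF file into transcript models."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True,
                            disable_infer_genes=True, disable_infer_transcripts=True)
    by_tx: dict[str, dict] = {}
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        tid = feat.attributes["transcript_id"][0]
        rec = by_tx.setdefault(tid, {
            "gene_id": feat.attributes["gene_id"][0],
            "chrom": feat.seqid,
            "strand": feat.strand,
            "biotype": feat.attributes.get("gene_biotype", ["unknown"])[0],
            "exons": [],
        })
        rec["exons"].append((feat.start - 1, feat.end))  # to 0-based half-open
    return [TranscriptModel(transcript_id=tid, **rec) for tid, rec in sorted(by_tx.items())]


def write_loci_bed(path, loci: Iterable[Locus]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for loc in loci:
            fh.write(f"{loc.chrom}\t{loc.span[0]}\t{loc.span[1]}\t{loc.locus_id}\n")


# ---------------------------------------------------------------------------
# Identification
# ---------------------------------------------------------------------------

def expand_coding_genes(
    transcripts: Sequence[TranscriptModel],
    coding_gene_ids: Iterable[str],
) -> dict[str, tuple[str, int, int]]:
    """Expanded territory per coding gene for defining intergenic space.

    A gene's territory is the union span of its own exons and the full spans
    of any transcripts sharing at least one exonic base with its exons. The
    expansion is applied once, not iterated to a fixed point.
    """
    coding = set(coding_gene_ids)
    exon_trees: dict[str, IntervalTree] = {}
    territories: dict[str, tuple[str, int, int]] = {}
    for t in transcripts:
        if t.gene_id in coding:
            tree = exon_trees.setdefault(t.chrom, IntervalTree())
            for a, b in t.exons:
                tree.addi(a, b, t.gene_id)
            s = territories.get(t.gene_id)
            lo, hi = t.span
            if s is None:
                territories[t.gene_id] = (t.chrom, lo, hi)
            else:
                territories[t.gene_id] = (s[0], min(s[1], lo), max(s[2], hi))
    for t in transcripts:
        if t.gene_id in coding:
            continue
        tree = exon_trees.get(t.chrom)
        if tree is None:
            continue
        hit_genes = {iv.data for a, b in t.exons for iv in tree.overlap(a, b)}
        for g in hit_genes:
            chrom, lo, hi = territories[g]
            territories[g] = (chrom, min(lo, t.span[0]), max(hi, t.span[1]))
    return territories


def identify_lincrna_candidates(
    transcripts: Sequence[TranscriptModel],
    territories: Mapping[str, tuple[str, int, int]],
    coding_gene_ids: Iterable[str],
    min_len: int = 200,
) -> list[TranscriptModel]:
    """Multiexonic intergenic noncoding transcripts longer than ``min_len``.

    A transcript is retained iff it has >= 2 exons, no exonic base inside any
    expanded coding territory, total exonic length strictly above ``min_len``
    and an external noncoding coding-potential label. Transcripts with an
    unset label are skipped with a warning.
    """
    coding = set(coding_gene_ids)
    terr_trees: dict[str, IntervalTree] = {}
    for chrom, lo, hi in territories.values():
        terr_trees.setdefault(chrom, IntervalTree()).addi(lo, hi)
    out = []
    for t in transcripts:
        if t.gene_id in coding:
            continue
        if len(t.exons) < 2 or t.exonic_length <= min_len:
            continue
        tree = terr_trees.get(t.chrom)
        if tree is not None and any(tree.overlap(a, b) for a, b in t.exons):
            continue
        if t.coding_label == "unset":
            logger.warning("%s skipped: coding potential not assessed", t.transcript_id)
            continue
        if t.coding_label != "noncoding":
            continue
        out.append(t)
    return out


def cluster_loci(candidates: Sequence[TranscriptModel]) -> list[Locus]:
    """Cluster candidates into loci: connected components under genomic-span
    overlap (>= 1 shared intronic or exonic base, strand-agnostic).

    Locus ids are assigned from the leftmost member, ``<chrom>:<start>``.
    """
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for t in candidates:
        by_chrom.setdefault(t.chrom, []).append(t)
    loci: list[Locus] = []
    for chrom in sorted(by_chrom):
        txs = sorted(by_chrom[chrom], key=lambda t: (t.span[0], t.span[1], t.transcript_id))
        cur: list[TranscriptModel] = []
        cur_end = -1
        for t in txs:
            lo, hi = t.span
            if cur and lo < cur_end:  # half-open: touching spans do not share a base
                cur.append(t)
                cur_end = max(cur_end, hi)
            else:
                if cur:
                    loci.append(_make_locus(chrom, cur))
                cur = [t]
                cur_end = hi
        if cur:
            loci.append(_make_locus(chrom, cur))
    return loci


def _make_locus(chrom: str, members: list[TranscriptModel]) -> Locus:
    lo = min(t.span[0] for t in members)
    hi = max(t.span[1] for t in members)
    return Locus(
        locus_id=f"{chrom}:{lo}",
        member_ids=tuple(t.transcript_id for t in members),
        chrom=chrom,
        span=(lo, hi),
    )


def orf_fraction(sequence: str) -> float:
    """Longest open reading frame length as a fraction of sequence length.

    A crude coding-potential heuristic used only for labelling synthetic
    transcripts (threshold 0.08: shorter ORFs are treated as noncoding).
    """
    seq = sequence.upper()
    stops = {"TAA", "TAG", "TGA"}
    best = 0
    for frame in range(3):
        start = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i:i + 3]
            if codon == "ATG" and start is None:
                start = i
            elif codon in stops and start is not None:
                best = max(best, i + 3 - start)
                start = None
    return best / len(seq) if seq else 0.0


# ---------------------------------------------------------------------------
# Positional enrichment tests
# ---------------------------------------------------------------------------

def _adjacent_gene_ids(
    gene_positions: Mapping[str, tuple[str, int, int]],
    loci: Sequence[Locus],
) -> set[str]:
    """Coding genes adjacent to >= 1 locus: in the per-chromosome ordering of
    genes and loci by start, a locus lies between the gene and the nearest
    coding gene on that side (no intervening coding gene)."""
    adjacent: set[str] = set()
    by_chrom: dict[str, list[tuple[int, str, str]]] = {}
    for gid, (chrom, lo, _hi) in gene_positions.items():
        by_chrom.setdefault(chrom, []).append((lo, "gene", gid))
    for loc in loci:
        by_chrom.setdefault(loc.chrom, []).append((loc.span[0], "locus", loc.locus_id))
    for chrom, items in by_chrom.items():
        items.sort()
        kinds = [k for _, k, _ in items]
        for i, (_, kind, ident) in enumerate(items):
            if kind != "gene":
                continue
            for step in (-1, 1):
                j = i + step
                while 0 <= j < len(items) and kinds[j] != "gene":
                    if kinds[j] == "locus":
                        adjacent.add(ident)
                        break
                    j += step
    return adjacent


def adjacency_enrichment(
    patterned_gene_ids: Iterable[str],
    gene_positions: Mapping[str, tuple[str, int, int]],
    loci: Sequence[Locus],
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Fold and empirical p for patterned genes being adjacent to lincRNA loci.

    The patterned label vector is permuted over all coding genes; fold is the
    observed adjacent-patterned fraction over the permutation mean, p is
    one-sided with the add-one rule.
    """
    patterned = set(patterned_gene_ids) & set(gene_positions)
    if len(patterned) < 2:
        raise ValueError("need >= 2 patterned genes")
    gene_ids = sorted(gene_positions)
    adjacent = _adjacent_gene_ids(gene_positions, loci)
    is_adj = np.array([g in adjacent for g in gene_ids])
    is_pat = np.array([g in patterned for g in gene_ids])
    observed = float(np.mean(is_adj[is_pat]))
    rng = np.random.default_rng(seed)
    n_pat = int(is_pat.sum())
    perm_stats = np.empty(n_perm)
    for k in range(n_perm):
        idx = rng.choice(len(gene_ids), size=n_pat, replace=False)
        perm_stats[k] = is_adj[idx].mean()
    fold = observed / float(perm_stats.mean()) if perm_stats.mean() > 0 else np.inf
    p = (1 + int(np.sum(perm_stats >= observed))) / (1 + n_perm)
    return float(fold), float(p)


def neighbor_correlation_test(
    pairs_patterned: Sequence[tuple[np.ndarray, np.ndarray]],
    pairs_unpatterned: Sequence[tuple[np.ndarray, np.ndarray]],
    method: str = "spearman",
) -> tuple[float, float]:
    """Are lincRNAs more strongly co-expressed with patterned neighbours?

    Per pair the absolute correlation (Spearman by default, Pearson behind the
    flag) of the two 7-sample profiles is computed; groups are compared with a
    one-sided rank-sum test (patterned > unpatterned). Constant profiles are
    dropped with a warning. Returns (rank-sum statistic, one-sided p).
    """
    def abs_corrs(pairs):
        vals = []
        for a, b in pairs:
            a = np.asarray(a, float)
            b = np.asarray(b, float)
            if np.std(a) == 0 or np.std(b) == 0:
                logger.warning("constant profile: pair dropped")
                continue
            if method == "spearman":
                r = stats.spearmanr(a, b).statistic
            elif method == "pearson":
                r = stats.pearsonr(a, b).statistic
            else:
                raise ValueError(f"unknown method {method!r}")
            vals.append(abs(float(r)))
        return vals

    g1 = abs_corrs(pairs_patterned)
    g2 = abs_corrs(pairs_unpatterned)
    if len(g1) < 3 or len(g2) < 3:
        raise ValueError("need >= 3 usable pairs per group")
    res = stats.mannwhitneyu(g1, g2, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def interval_overlap_enrichment(
    query_intervals: Sequence[tuple[str, int, int]],
    feature_intervals: Sequence[tuple[str, int, int]],
    chrom_sizes: Mapping[str, int],
    n_shuffles: int = 1_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Overlap enrichment of query intervals with a feature set.

    The statistic is the number of query intervals overlapping >= 1 feature.
    The null re-places each query uniformly within its chromosome, preserving
    lengths. Fold = observed / mean(shuffled); one-sided add-one empirical p.
    """
    for chrom, a, b in query_intervals:
        if b - a > chrom_sizes[chrom]:
            raise ValueError(f"interval ({chrom}, {a}, {b}) longer than chromosome")
        if a < 0 or b > chrom_sizes[chrom]:
            raise ValueError(f"interval ({chrom}, {a}, {b}) outside chromosome")
    # merged feature intervals per chromosome for fast overlap queries
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, a, b in feature_intervals:
        by_chrom.setdefault(chrom, []).append((a, b))
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts, ends = [], []
        for a, b in ivs:
            if ends and a <= ends[-1]:
                ends[-1] = max(ends[-1], b)
            else:
                starts.append(a)
                ends.append(b)
        merged[chrom] = (np.array(starts), np.array(ends))

    def count(queries: Sequence[tuple[str, int, int]]) -> int:
        c = 0
        for chrom, a, b in queries:
            if chrom not in merged:
                continue
            starts, ends = merged[chrom]
            # merged intervals are disjoint and sorted, so ends are sorted too;
            # overlap iff some feature has start < b and end > a
            i = int(np.searchsorted(starts, b))  # first feature starting at/after b
            if i > 0 and ends[i - 1] > a:
                c += 1
        return c

    observed = count(query_intervals)
    rng = np.random.default_rng(seed)
    shuffled = np.empty(n_shuffles)
    chroms = [q[0] for q in query_intervals]
    lengths = [q[2] - q[1] for q in query_intervals]
    for k in range(n_shuffles):
        placed = []
        for chrom, L in zip(chroms, lengths):
            start = int(rng.integers(0, chrom_sizes[chrom] - L + 1))
            placed.append((chrom, start, start + L))
        shuffled[k] = count(placed)
    mean_null = float(shuffled.mean())
    fold = observed / mean_null if mean_null > 0 else np.inf
    p = (1 + int(np.sum(shuffled >= observed))) / (1 + n_shuffles)
    return float(fold), float(p)
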