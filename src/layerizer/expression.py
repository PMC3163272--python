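"""Quantification tables, curations, expression filters and laminar summaries.

The unit of computation is a :class:`QuantRecord`: one gene or transcript with
an FPKM point estimate and a 95% confidence interval per dissected sample.
Samples are ordered superficial-to-deep (``A, B1, B2, C, D, E, F``); ``B1`` and
``B2`` are biological replicates of the second laminar segment and are kept as
separate feature dimensions throughout.

Two filters gate everything downstream:

* *expressed*: maximum FPKM across samples strictly above a floor (0.1 FPKM);
* *classifiable*: the widest 95% CI across samples is at most half the mean
  FPKM across samples, so quantification uncertainty is small relative to the
  expression level.

The laminar summary heat statistic summarises, per sample and curated layer
class, the median fractional expression of the class's genes, centred and
scaled by the across-class mean for that sample.
"""

from __future__ import annotations

import io
import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Ordered dissected samples, superficial to deep. B1/B2 are replicates.
DEFAULT_SAMPLES: tuple[str, ...] = ("A", "B1", "B2", "C", "D", "E", "F")

#: The five trainable layer classes. Layer 1 has no curated markers.
LAYERS: tuple[str, ...] = ("L2/3", "L4", "L5", "L6", "L6b")

NO_ENRICHMENT = "no_enrichment"

#: Classifier classes: five layers plus the unpatterned class.
CLASSES: tuple[str, ...] = LAYERS + (NO_ENRICHMENT,)

#: Default sample -> layer correspondence for overlapping dissections.
DEFAULT_SAMPLE_LAYER_MAP: dict[str, frozenset[str]] = {
    "A": frozenset({"L1", "L2/3"}),
    "B1": frozenset({"L2/3", "L4"}),
    "B2": frozenset({"L2/3", "L4"}),
    "C": frozenset({"L4", "L5"}),
    "D": frozenset({"L5"}),
    "E": frozenset({"L6"}),
    "F": frozenset({"L6b"}),
}


@dataclass(frozen=True)
class SampleSet:
    """Ordered sample identifiers with an optional layer correspondence."""

    names: tuple[str, ...] = DEFAULT_SAMPLES
    layer_map: Mapping[str, frozenset[str]] | None = None

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("sample identifiers must be unique")
        if self.layer_map is not None:
            unknown = set(self.layer_map) - set(self.names)
            if unknown:
                raise ValueError(f"layer_map references unknown samples: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass
class QuantRecord:
    """One feature's FPKM and 95% CI across the ordered sample set."""

    feature_id: str
    feature_kind: str  # "gene" | "transcript"
    gene_id: str
    fpkm: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray

    def __post_init__(self) -> None:
        self.fpkm = np.asarray(self.fpkm, dtype=float)
        self.ci_lo = np.asarray(self.ci_lo, dtype=float)
        self.ci_hi = np.asarray(self.ci_hi, dtype=float)
        if not (self.fpkm.shape == self.ci_lo.shape == self.ci_hi.shape):
            raise ValueError(f"{self.feature_id}: fpkm/ci vectors must share a shape")
        if self.feature_kind not in ("gene", "transcript"):
            raise ValueError(f"{self.feature_id}: feature_kind must be gene or transcript")
        for name, v in (("fpkm", self.fpkm), ("ci_lo", self.ci_lo), ("ci_hi", self.ci_hi)):
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{self.feature_id}: non-finite {name}")
            if np.any(v < 0):
                raise ValueError(f"{self.feature_id}: negative {name}")
        if np.any(self.ci_lo > self.fpkm) or np.any(self.fpkm > self.ci_hi):
            raise ValueError(f"{self.feature_id}: CI does not bracket FPKM")

    @property
    def n_samples(self) -> int:
        return self.fpkm.size


@dataclass(frozen=True)
class CurationLabel:
    """Gold-standard layer-enrichment annotation for one gene.

    Either the gene is curated as enriched in one or more of the five layers,
    or it is curated as showing no layer enrichment — never both.
    """

    gene_id: str
    enriched_layers: frozenset[str] = frozenset()
    no_enrichment: bool = False

    def __post_init__(self) -> None:
        if self.no_enrichment == bool(self.enriched_layers):
            raise ValueError(
                f"{self.gene_id}: exactly one of no_enrichment / enriched_layers required"
            )
        bad = self.enriched_layers - set(LAYERS)
        if bad:
            raise ValueError(f"{self.gene_id}: unknown layers {sorted(bad)}")

    def is_positive_for(self, cls: str) -> bool:
        """Whether this curation is a positive example for the ``cls`` classifier."""
        if cls == NO_ENRICHMENT:
            return self.no_enrichment
        return cls in self.enriched_layers


# ---------------------------------------------------------------------------
# Filters and per-record features
# ---------------------------------------------------------------------------

def is_expressed(rec: QuantRecord, threshold: float = 0.1) -> bool:
    """True if the feature's maximum FPKM is strictly above ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return bool(np.max(rec.fpkm) > threshold)


def is_classifiable(rec: QuantRecord) -> bool:
    """CI-width filter: widest 95% CI at most half the mean FPKM (inclusive).

    An all-zero record passes vacuously (0 <= 0); the pipeline removes such
    records with :func:`is_expressed` first.
    """
    widths = rec.ci_hi - rec.ci_lo
    return bool(np.max(widths) <= 0.5 * np.mean(rec.fpkm))


def fractional_profile(rec: QuantRecord) -> np.ndarray:
    """Fractional expression per sample: FPKM divided by the across-sample sum."""
    total = float(np.sum(rec.fpkm))
    if total <= 0:
        raise ValueError(f"{rec.feature_id}: zero expression")
    return rec.fpkm / total


def heat_statistic(
    curations: Iterable[CurationLabel],
    quant_table: Iterable[QuantRecord],
    samples: SampleSet | None = None,
    classes: Sequence[str] = CLASSES,
) -> pd.DataFrame:
    """Laminar summary heat values, samples x curated classes.

    For each class *l*, ``t_sl`` is the median fractional expression in sample
    *s* over expressed genes curated to *l*; the heat value is
    ``(t_sl - mean_l t_sl) / mean_l t_sl`` with the mean over classes within
    each sample, so every sample's row of heat values averages to zero.
    """
    samples = samples or SampleSet()
    by_gene = {r.feature_id: r for r in quant_table if r.feature_kind == "gene"}
    t = np.full((len(samples), len(classes)), np.nan)
    cur_list = list(curations)
    for j, cls in enumerate(classes):
        profiles = []
        for cur in cur_list:
            if not cur.is_positive_for(cls):
                continue
            rec = by_gene.get(cur.gene_id)
            if rec is None or not is_expressed(rec):
                continue
            profiles.append(fractional_profile(rec))
        if not profiles:
            raise ValueError(f"no curated, expressed gene for class {cls!r}")
        t[:, j] = np.median(np.vstack(profiles), axis=0)
    row_mean = t.mean(axis=1, keepdims=True)
    heat = (t - row_mean) / row_mean
    return pd.DataFrame(heat, index=list(samples.names), columns=list(classes))


# ---------------------------------------------------------------------------
# Tab-separated I/O
# ---------------------------------------------------------------------------

def write_quant_tsv(path, records: Iterable[QuantRecord], samples: SampleSet | None = None,
                    header_comments: Sequence[str] = ()) -> None:
    """Write a quantification table: id columns then fpkm/lo/hi triplets per sample.

    Values are written with Python's shortest round-trip float representation,
    so a write/read cycle is bit-exact.
    """
    samples = samples or SampleSet()
    cols = ["feature_id", "feature_kind", "gene_id"]
    for s in samples.names:
        cols += [f"fpkm_{s}", f"lo_{s}", f"hi_{s}"]
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        fh.write("\t".join(cols) + "\n")
        for r in records:
            row = [r.feature_id, r.feature_kind, r.gene_id]
            for i in range(len(samples)):
                row += [repr(float(r.fpkm[i])), repr(float(r.ci_lo[i])), repr(float(r.ci_hi[i]))]
            fh.write("\t".join(row) + "\n")


def read_quant_tsv(path) -> tuple[list[QuantRecord], SampleSet]:
    with open(path, encoding="utf-8") as fh:
        text = [ln for ln in fh if not ln.startswith("#")]
    df = pd.read_csv(io.StringIO("".join(text)), sep="\t", float_precision="round_trip",
                     dtype={"feature_id": str, "feature_kind": str, "gene_id": str})
    sample_names = tuple(c[5:] for c in df.columns if c.startswith("fpkm_"))
    samples = SampleSet(names=sample_names)
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        records.append(QuantRecord(
            feature_id=d["feature_id"], feature_kind=d["feature_kind"], gene_id=d["gene_id"],
            fpkm=np.array([d[f"fpkm_{s}"] for s in sample_names], dtype=float),
            ci_lo=np.array([d[f"lo_{s}"] for s in sample_names], dtype=float),
            ci_hi=np.array([d[f"hi_{s}"] for s in sample_names], dtype=float),
        ))
    return records, samples


def write_curation_tsv(path, curations: Iterable[CurationLabel],
                       header_comments: Sequence[str] = ()) -> None:
    """Curations: gene_id, then semicolon-joined layers or the word ``none``."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        fh.write("gene_id\tenriched_layers\n")
        for c in curations:
            label = "none" if c.no_enrichment else ";".join(sorted(c.enriched_layers))
            fh.write(f"{c.gene_id}\t{label}\n")


def read_curation_tsv(path) -> list[CurationLabel]:
    out: list[CurationLabel] = []
    with open(path, encoding="utf-8") as fh:
        header_seen = False
        for ln in fh:
            ln = ln.rstrip("\n")
            if not ln or ln.startswith("#"):
                continue
            if not header_seen:
                header_seen = True
                continue
            gene_id, label = ln.split("\t")
            if label == "none":
                out.append(CurationLabel(gene_id=gene_id, no_enrichment=True))
            else:
                out.append(CurationLabel(gene_id=gene_id,
                                         enriched_layers=frozenset(label.split(";"))))
    return out
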