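"""Functional enrichment with a classifier-bias-corrected simulation null.

Two families of tests:

* patterned vs unpatterned gene sets, per term, by a two-sided Fisher exact
  test gated on power (a term is only tested if the most extreme 2x2 table
  compatible with the margins could reach p < 0.05);
* per-layer enrichment against a simulated null that corrects for classifier
  bias: simulated draws come from the set of all classifiable genes with
  probability equal to the classifier's precision, and otherwise from the
  predicted set of a contaminating class, weighted by the cross-validation
  false-positive source distribution. One-sided empirical p-values use the
  add-one estimator; q-values follow Storey's procedure with a single
  lambda = 0.5.

"Conditional" databases (GO, knockout phenotypes) restrict backgrounds to
genes carrying at least one annotation in that database; in the simulation,
unannotated draws are rejected until the annotated draw count matches the
predicted set's.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Mapping, Sequence, Set
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .classifier import CVReport
from .expression import CLASSES

logger = logging.getLogger(__name__)


@dataclass
class TermDB:
    """Named gene sets with a conditional-background flag."""

    name: str
    conditional: bool
    terms: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for term, genes in self.terms.items():
            if not genes:
                raise ValueError(f"{self.name}/{term}: empty gene set")

    @property
    def annotated_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.terms.values():
            out |= genes
        return frozenset(out)


def write_termdb_tsv(path, db: TermDB) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# database={db.name}\n")
        fh.write(f"# conditional={'true' if db.conditional else 'false'}\n")
        fh.write("term\tgenes\n")
        for term in sorted(db.terms):
            fh.write(f"{term}\t{';'.join(sorted(db.terms[term]))}\n")


def read_termdb_tsv(path) -> TermDB:
    name, conditional = "unnamed", False
    terms: dict[str, frozenset[str]] = {}
    header_seen = False
    with open(path, encoding="utf-8") as fh:
        for ln in fh:
            ln = ln.rstrip("\n")
            if ln.startswith("#"):
                body = ln.lstrip("# ")
                if body.startswith("database="):
                    name = body.split("=", 1)[1]
                elif body.startswith("conditional="):
                    conditional = body.split("=", 1)[1].lower() == "true"
                continue
            if not ln:
                continue
            if not header_seen:
                header_seen = True
                continue
            term, genes = ln.split("\t")
            terms[term] = frozenset(genes.split(";"))
    return TermDB(name=name, conditional=conditional, terms=terms)


@dataclass
class EnrichmentResult:
    term: str
    counts: tuple[int, ...]
    fold_enrichment: float
    p: float
    q: float | None
    direction: str  # "enriched" | "depleted"
    test_kind: str  # "fisher" | "simulation"


# ---------------------------------------------------------------------------
# Fisher tests (patterned vs unpatterned)
# ---------------------------------------------------------------------------

def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by the minimum-likelihood convention."""
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def power_gate(term_count: int, background_size: int,
               set1_size: int, set2_size: int, alpha: float = 0.05) -> bool:
    """True if some 2x2 table with these margins reaches two-sided p < alpha.

    The most extreme tables place as many term genes as possible in one set;
    both extremes are checked.
    """
    if term_count < 0 or term_count > background_size:
        raise ValueError("term_count must lie in [0, background_size]")
    if set1_size + set2_size != background_size:
        raise ValueError("set sizes must partition the background")
    if term_count == 0:
        return False
    best = 1.0
    for a in (min(term_count, set1_size), max(0, term_count - set2_size)):
        b = term_count - a
        c = set1_size - a
        d = set2_size - b
        best = min(best, fisher_two_sided(a, b, c, d))
    return best < alpha


def fisher_patterned(
    term: str,
    term_genes: Set[str],
    patterned: Set[str],
    unpatterned: Set[str],
    db: TermDB,
) -> EnrichmentResult:
    """Two-sided Fisher test of a term between patterned and unpatterned sets.

    For a conditional database both sets are restricted to genes annotated
    anywhere in the database. Fold enrichment is observed over expected
    patterned-with-term count under independence.
    """
    if db.conditional:
        annotated = db.annotated_genes
        patterned = set(patterned) & annotated
        unpatterned = set(unpatterned) & annotated
    a = len(set(patterned) & term_genes)
    b = len(set(unpatterned) & term_genes)
    c = len(patterned) - a
    d = len(unpatterned) - b
    n = a + b + c + d
    if (a + c) == 0 or (b + d) == 0 or (a + b) == 0:
        raise ValueError(f"{term}: empty margin")
    p = fisher_two_sided(a, b, c, d)
    expected = (a + b) * (a + c) / n
    fold = a / expected if expected > 0 else math.inf
    return EnrichmentResult(
        term=term, counts=(a, b, c, d), fold_enrichment=fold, p=p, q=None,
        direction="enriched" if a >= expected else "depleted", test_kind="fisher")


# ---------------------------------------------------------------------------
# Bias-corrected simulation null (per-layer enrichment)
# ---------------------------------------------------------------------------

@dataclass
class NullSpec:
    """Simulation parameters for one layer's bias-corrected null."""

    layer: str
    precision: float
    contamination: dict[str, float]
    n_sims: int = 200_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.precision <= 1.0):
            raise ValueError("precision must be in [0, 1]")
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        total = sum(self.contamination.values())
        if self.contamination and abs(total - 1.0) > 1e-9:
            raise ValueError("contamination must sum to 1")


def build_null_spec(cv: CVReport, n_sims: int = 200_000, seed: int = 0) -> NullSpec:
    """Derive the null from cross-validation: precision and the false-positive
    source distribution. A perfect classifier (no false positives) falls back
    to uniform contamination over the other classes."""
    contamination = dict(cv.contamination)
    if not contamination:
        others = [c for c in CLASSES if c != cv.layer]
        contamination = {c: 1.0 / len(others) for c in others}
        logger.warning("%s: no false positives in CV; contamination set uniform", cv.layer)
    return NullSpec(layer=cv.layer, precision=cv.precision,
                    contamination=contamination, n_sims=n_sims, seed=seed)


def simulate_layer_null(
    predicted_sets: Mapping[str, Set[str]],
    all_classifiable: Sequence[str] | Set[str],
    term_genes: Set[str],
    spec: NullSpec,
    conditional: bool = False,
    annotated_genes: Set[str] | None = None,
    return_counts: bool = False,
):
    """One-sided empirical p that the layer's predicted set over-contains a term.

    Each simulation draws ``|predicted set|`` genes with replacement: with
    probability equal to the classifier's precision, uniformly from all
    classifiable genes; otherwise from the predicted set of a contaminating
    class chosen by the contamination distribution. For a conditional database
    unannotated draws are rejected until the annotated draw count matches the
    predicted set's annotated count, and only annotated genes are tallied.

    Because draws are independent given their source, each simulation is
    realised by drawing per-source draw counts (multinomial) and per-source
    term hits (binomial) — distributionally identical to drawing individual
    gene identifiers.

    p = (1 + #{simulated count >= observed}) / (1 + n_sims).
    """
    rng = np.random.default_rng(spec.seed)
    universe = set(all_classifiable)
    predicted = set(predicted_sets[spec.layer])
    if not predicted:
        raise ValueError(f"{spec.layer}: empty predicted set")
    term_in_universe = set(term_genes) & universe

    if conditional:
        if annotated_genes is None:
            raise ValueError("conditional simulation requires annotated_genes")
        annotated = set(annotated_genes) & universe
        observed = len(predicted & term_in_universe & annotated)
        n_target = len(predicted & annotated)
    else:
        annotated = universe
        observed = len(predicted & term_in_universe)
        n_target = len(predicted)

    if n_target == 0 or not term_in_universe:
        p = 1.0
        counts = np.zeros(spec.n_sims, dtype=int)
        return (p, counts) if return_counts else p

    # Source mixture: the classifiable universe with weight = precision, then
    # each contaminating class's predicted set.
    sources: list[tuple[float, set[str]]] = [(spec.precision, universe)]
    for cls, w in sorted(spec.contamination.items()):
        pool = set(predicted_sets.get(cls, set()))
        if pool:
            sources.append(((1.0 - spec.precision) * w, pool))
    weights = np.array([w for w, _ in sources])
    if weights.sum() <= 0:
        raise ValueError("degenerate source mixture")
    # per-source P(annotated) and P(term | annotated); term genes are annotated
    p_ann = np.array([len(pool & annotated) / len(pool) for _, pool in sources])
    p_term_ann = np.array([
        (len(pool & term_in_universe & annotated) / len(pool & annotated))
        if len(pool & annotated) else 0.0
        for _, pool in sources])
    # rejection of unannotated draws conditions the source mixture on annotation
    cond_w = weights * p_ann
    if cond_w.sum() <= 0:
        p = 1.0
        counts = np.zeros(spec.n_sims, dtype=int)
        return (p, counts) if return_counts else p
    cond_w = cond_w / cond_w.sum()

    draws = rng.multinomial(n_target, cond_w, size=spec.n_sims)
    counts = np.zeros(spec.n_sims, dtype=int)
    for k in range(len(sources)):
        if p_term_ann[k] > 0:
            counts += rng.binomial(draws[:, k], p_term_ann[k])
    p = float((1 + int(np.sum(counts >= observed))) / (1 + spec.n_sims))
    return (p, counts) if return_counts else p


# ---------------------------------------------------------------------------
# Multiple testing and concordance
# ---------------------------------------------------------------------------

def qvalues(p: Sequence[float]) -> np.ndarray:
    """Storey q-values with a single lambda = 0.5.

    pi0 = min(1, mean(p > 0.5) / 0.5); q_(i) = min_{j >= i} pi0 * m * p_(j) / j
    over the ascending order statistics. Monotone in p, clipped to [0, 1].
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p values must lie in (0, 1]")
    m = p.size
    pi0 = min(1.0, float(np.mean(p > 0.5)) / 0.5)
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def binomial_concordance(k: int, n: int) -> tuple[int, float]:
    """Percent concordant (rounded half away from zero) and the exact
    two-tailed binomial p-value against probability 0.5."""
    if not (0 <= k <= n) or n < 1:
        raise ValueError("require 0 <= k <= n, n >= 1")
    percent = (200 * k + n) // (2 * n)
    p = float(stats.binomtest(k, n, 0.5, alternative="two-sided").pvalue)
    return int(percent), p


@dataclass
class ConcordanceReport:
    overall: float | None
    enriched: float | None


def concordance_metrics(
    enriched_a: Set[str],
    enriched_b: Set[str],
    classified_a: Set[str],
    classified_b: Set[str],
) -> ConcordanceReport:
    """Overall and enriched concordance between two prediction runs.

    Overall = (both enriched + both unenriched) / genes classified in both.
    Enriched = mean of both/(both + a-only) and both/(both + b-only); a
    component with zero denominator is undefined and drops the metric to the
    remaining information (reported as None when neither side is defined).
    """
    shared = set(classified_a) & set(classified_b)
    if not shared:
        raise ValueError("no genes classified in both runs")
    ea = set(enriched_a) & shared
    eb = set(enriched_b) & shared
    both = len(ea & eb)
    neither = len(shared - ea - eb)
    overall = (both + neither) / len(shared)
    a_only = len(ea - eb)
    b_only = len(eb - ea)
    comps = []
    for only in (a_only, b_only):
        denom = both + only
        comps.append(both / denom if denom else None)
    defined = [c for c in comps if c is not None]
    enriched = sum(defined) / len(defined) if defined else None
    return ConcordanceReport(overall=overall, enriched=enriched)
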