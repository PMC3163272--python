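"""Shared fixtures: small synthetic atlases and fitted classifiers."""

import numpy as np
import pytest

import layerizer as lz

#: One-to-one sample -> layer mapping: each layer has a sole sample.
ONE_TO_ONE_MAP = (
    ("A", ("L1",)),
    ("B1", ("L2/3",)),
    ("B2", ("L2/3",)),
    ("C", ("L4",)),
    ("D", ("L5",)),
    ("E", ("L6",)),
    ("F", ("L6b",)),
)


def make_record(fpkm, lo=None, hi=None, feature_id="f1", kind="gene", gene_id=None):
    fpkm = np.asarray(fpkm, dtype=float)
    if lo is None:
        lo = fpkm
    if hi is None:
        hi = fpkm
    return lz.QuantRecord(feature_id=feature_id, feature_kind=kind,
                          gene_id=gene_id or feature_id,
                          fpkm=fpkm, ci_lo=np.asarray(lo, float), ci_hi=np.asarray(hi, float))


@pytest.fixture(scope="session")
def small_atlas():
    """40 genes per class, moderate noise; enough signal for clean classifiers."""
    cfg = lz.AtlasConfig(n_genes_per_class=40, n_l1_genes=10, noise_sd=0.25,
                         label_noise_rate=0.05, n_switch_genes=3, seed=123)
    return lz.generate_atlas(cfg)


@pytest.fixture(scope="session")
def noise_free_atlas():
    """Noise-free atlas under the one-to-one mapping: exact enrichment folds."""
    cfg = lz.AtlasConfig(n_genes_per_class=25, n_l1_genes=5, noise_sd=0.0,
                         label_noise_rate=0.0, sample_layer_map=ONE_TO_ONE_MAP,
                         seed=5)
    return lz.generate_atlas(cfg)


@pytest.fixture(scope="session")
def fitted_small(small_atlas):
    cur = {c.gene_id: c for c in small_atlas.curations}
    genes = [r for r in small_atlas.quant_table if r.feature_kind == "gene"]
    usable = [r for r in genes if lz.is_expressed(r) and lz.is_classifiable(r)]
    curated = [r for r in usable if r.feature_id in cur]
    fitted = lz.fit_layer_models(curated, cur, seed=9, folds=5)
    return small_atlas, curated, cur, fitted
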