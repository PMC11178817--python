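import numpy as np
import pandas as pd
import pytest

from atlasfuse.atlas import Ontology, Parcellation, ReferenceSpace, RegionNode
from atlasfuse.ingest import ExpressionDataset


@pytest.fixture
def small_ontology():
    """root(1) -> {A(2) -> {A1(4), A2(5)}, B(3) -> {B1(6), B2(7)}}."""
    return Ontology(
        [
            RegionNode(1, "root", "rt", None),
            RegionNode(2, "A", "a", 1),
            RegionNode(3, "B", "b", 1),
            RegionNode(4, "A1", "a1", 2),
            RegionNode(5, "A2", "a2", 2),
            RegionNode(6, "B1", "b1", 3),
            RegionNode(7, "B2", "b2", 3),
        ]
    )


@pytest.fixture
def small_parcellation(small_ontology):
    """4x4x4 grid whose flattened quarters are labelled A1, A2, B1, B2."""
    labels = np.empty(64, dtype=np.int32)
    for leaf, chunk in zip([4, 5, 6, 7], np.array_split(np.arange(64), 4)):
        labels[chunk] = leaf
    return Parcellation(ReferenceSpace((4, 4, 4)), labels.reshape(4, 4, 4))


def make_random_dataset(rng, n_genes=10, leaves=(4, 5, 6, 7), cell_types=("exc", "inh"),
                        n_per_group=3, ontology=None):
    """Small annotated dataset with uniform random positive values."""
    cols, meta_rows, sids = {}, [], []
    k = 0
    for leaf in leaves:
        for ct in cell_types:
            for _ in range(n_per_group):
                sid = f"s{k:04d}"
                cols[sid] = rng.uniform(0.1, 10.0, size=n_genes)
                meta_rows.append({"cell_type": ct, "age": rng.choice(["young", "adult"]),
                                  "phenotype": "control", "region_id": leaf})
                sids.append(sid)
                k += 1
    values = pd.DataFrame(cols, index=[f"g{i:03d}" for i in range(n_genes)])
    meta = pd.DataFrame(meta_rows, index=sids)
    return ExpressionDataset(values=values, sample_meta=meta, norm="cpm", name="fixture")


@pytest.fixture
def random_dataset(small_ontology):
    return make_random_dataset(np.random.default_rng(7), ontology=small_ontology)
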