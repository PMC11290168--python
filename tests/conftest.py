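import numpy as np
import pytest

import grnkit as gk


@pytest.fixture
def tiny_mask() -> gk.AnnotationMask:
    # 3 SNPs, 2 genes; snp1,snp2 -> geneA; snp3 -> geneB
    return gk.AnnotationMask(
        row_ids=["snp1", "snp2", "snp3"],
        col_ids=["geneA", "geneB"],
        values=np.array([[1, 0], [1, 0], [0, 1]]),
    )


@pytest.fixture
def small_dataset() -> gk.GenotypeDataset:
    rng = np.random.default_rng(42)
    X = rng.integers(0, 3, size=(30, 3)).astype(float)
    return gk.GenotypeDataset(
        sample_ids=[f"s{i}" for i in range(30)],
        variable_ids=["snp1", "snp2", "snp3"],
        X=X,
        y=rng.standard_normal(30),
        family=["f1"] * 15 + ["f2"] * 15,
    )


def random_grn(rng: np.random.Generator) -> gk.GRN:
    """A random valid GRN for round-trip property tests."""
    n1 = int(rng.integers(0, 5))
    n2 = int(rng.integers(0, 4))
    kind = rng.choice(["pip", "pvalue"])
    l2_ids = [f"g{k}" for k in range(n2)]
    nodes = []
    for k in range(n1):
        score = float(rng.random()) if kind == "pip" else float(rng.uniform(1e-6, 1))
        memberships = tuple(
            g for g in l2_ids if rng.random() < 0.5
        )
        nodes.append(
            gk.GRNNode(
                id=f"v{k}", level=1, score=score, score_kind=str(kind),
                significant=True, group_memberships=memberships,
                orphan=bool(rng.random() < 0.2),
            )
        )
    for g in l2_ids:
        score = float(rng.random()) if kind == "pip" else float(rng.uniform(1e-6, 1))
        nodes.append(
            gk.GRNNode(
                id=g, level=2, score=score, score_kind=str(kind), significant=True
            )
        )
    edges = []
    for k in range(n1):
        for g in l2_ids:
            if rng.random() < 0.4:
                edges.append(
                    gk.GRNEdge(
                        source=f"v{k}", target=g, directed=True, kind="cross_level"
                    )
                )
    for a in range(n2):
        for b in range(a + 1, n2):
            if rng.random() < 0.4:
                w = float(rng.random()) if rng.random() < 0.5 else None
                edges.append(
                    gk.GRNEdge(
                        source=l2_ids[a], target=l2_ids[b], directed=False,
                        kind="within_level", weight=w,
                    )
                )
    metadata = {
        "l1_cutoff": 0.5,
        "l2_cutoff": 0.5,
        "layout": str(rng.choice(["layout_with_kk", "layout_circle"])),
        "backend": "ssvi",
    }
    return gk.GRN(nodes=nodes, edges=edges, metadata=metadata)
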