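import numpy as np
import pytest

import cosinet as cn
from cosinet.dce import build_dce_network
from cosinet.synthetic import default_scenario


@pytest.fixture
def tiny_expr():
    """4 genes x 12 samples, two conditions of 6, deterministic values."""
    rng = np.random.default_rng(99)
    values = 5 + 2 * rng.standard_normal((4, 12))
    genes = ["gA", "gB", "gC", "gD"]
    samples = [f"s{i}" for i in range(12)]
    expr = cn.ExpressionMatrix(values, genes, samples)
    design = cn.ConditionDesign(
        {s: ("x" if i < 6 else "y") for i, s in enumerate(samples)}, "x", "y"
    )
    return expr, design


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline on the reference planted scenario (one fixed seed).

    Computed once per session; several tests inspect different stages.
    """
    expr, design, collection, truth = cn.simulate_scenario(default_scenario(11))
    Z, corr1, corr2, filtered = build_dce_network(expr, design)
    cent = cn.power_iteration_centrality(Z)
    ranking = cn.rank_genes(cent)
    records = cn.gsea_preranked(ranking, collection, n_perm=10000, seed=11)
    top = records[0]
    sub = cn.build_subnetwork(Z, top.leading_edge, t=3.0, corr1=corr1, corr2=corr2)
    table = cn.score_all_samples(filtered, design, sub)
    return {
        "expr": expr,
        "design": design,
        "collection": collection,
        "truth": truth,
        "Z": Z,
        "corr1": corr1,
        "corr2": corr2,
        "filtered": filtered,
        "centrality": cent,
        "ranking": ranking,
        "records": records,
        "subnetwork": sub,
        "scores": table,
    }
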