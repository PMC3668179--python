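import logging

import numpy as np
import pytest
from skbio import TreeNode

from arisakit.clone_library import make_clone_record

logging.disable(logging.WARNING)


def make_clone(clone_id, sample_id, igs_len, core, rng=None, igs=None):
    """Clone with a chosen 23S core (padded/truncated to 131 bp)."""
    core = (core * 131)[:131]
    if igs is None:
        rng = rng or np.random.default_rng(abs(hash(clone_id)) % 2**31)
        igs = "".join(rng.choice(list("ACGT"), size=igs_len))
    return make_clone_record(clone_id, sample_id, igs + core)


def random_bifurcating_tree(rng, n_leaves, prefix="L"):
    nodes = [TreeNode(name=f"{prefix}{i}") for i in range(n_leaves)]
    for nd in nodes:
        nd.length = float(rng.exponential(0.1) + 0.01)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(children=[a, b])
        parent.length = float(rng.exponential(0.1) + 0.01)
        nodes.append(parent)
    nodes[0].length = None
    return nodes[0]


def caterpillar_tree(n_leaves):
    s = "L0:1"
    for i in range(1, n_leaves):
        s = f"({s},L{i}:1):1"
    return TreeNode.read([s + ";"])


@pytest.fixture(scope="session")
def zero_noise_replicates():
    """Twenty zero-noise synthetic studies pushed through the full pipeline."""
    from arisakit.pipeline import AnalysisParams, analyze
    from arisakit.synthetic import SimConfig, simulate_dataset, truth_report

    cfg = SimConfig().zero_noise()
    out = []
    for k in range(20):
        seed = 1000 + k
        ds = simulate_dataset(cfg, seed=seed)
        res = analyze(
            ds.clones, ds.profiles, ds.metadata, ds.hits, ds.tree,
            ds.reference_lineages,
            params=AnalysisParams(seed=seed, community=True),
        )
        rep = truth_report(ds.truth, res.presence, res.otus, res.contaminants)
        out.append((ds, res, rep))
    return out
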