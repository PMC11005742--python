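"""Shared fixtures: random haplotype windows and the desk-scale study data.

The heavyweight session fixtures (featurized 5-class dataset, trained
architecture comparison) are lazy: only tests that request them pay their
cost, and they are computed once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from sweepdann import dann, featengine, simdata
from sweepdann.haplotypes import HaplotypeWindow
from sweepdann.scanio import featurize_split
from sweepdann.simdata import ScenarioParams

# desk-scale study conditions (see docs/methods.md): 40 haplotypes, 100 kb
# fragments, 64 feature windows of 11 SNPs, 64 positional intervals
SMALL_SPEC = featengine.FragmentSpec(n=64, k=5, m=64)
ARCH_KINDS = ("ours", "cnn2d", "cnn1d", "rnn")


def random_window(
    rng: np.random.Generator,
    n_hap: int | None = None,
    n_sites: int | None = None,
    length: float = 1000.0,
) -> HaplotypeWindow:
    """A random polymorphic haplotype matrix (every column segregating)."""
    n_hap = n_hap or int(rng.integers(4, 12))
    n_sites = n_sites or int(rng.integers(3, 15))
    counts = rng.integers(1, n_hap, size=n_sites)
    matrix = np.zeros((n_hap, n_sites), dtype=np.int8)
    for j, c in enumerate(counts):
        matrix[rng.choice(n_hap, size=c, replace=False), j] = 1
    positions = np.sort(rng.uniform(0, length, size=n_sites))
    positions += np.arange(n_sites) * 1e-9  # strictness under ties
    return HaplotypeWindow(matrix, positions, (0.0, length))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def study_feats():
    """200 cases/class (140/30/30 split) featurized at the desk-scale spec."""
    params = ScenarioParams()
    cases = simdata.generate_cases(params, 200, seed=11)
    split = simdata.make_splits(cases, (140, 30, 30), seed=12)
    return featurize_split(split, SMALL_SPEC)


@pytest.fixture(scope="session")
def arch_comparison(study_feats):
    """Mean test accuracy of each feature-extractor architecture, 3 seeds."""
    ys = np.asarray(study_feats["train"].labels)
    yv = np.asarray(study_feats["validation"].labels)
    yt = np.asarray(study_feats["test"].labels)
    results = {}
    models = {}
    for kind in ARCH_KINDS:
        accs = []
        for seed in (0, 1, 2):
            cfg = dann.ModelConfig(
                extractor=kind, lam=0.0, M=1, epochs=50, patience=12,
                batch_size=64, seed=seed, dropout=0.4,
            )
            model = dann.DannModel(cfg, m=SMALL_SPEC.m, n_stats=40)
            model.fit(study_feats["train"].X, ys, study_feats["validation"].X, yv,
                      None, adversarial=False)
            accs.append(model.evaluate(study_feats["test"].X, yt)[1])
            if kind == "ours" and seed == 0:
                models["ours"] = model
        results[kind] = float(np.mean(accs))
    return {"mean_acc": results, "model_ours": models["ours"]}
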