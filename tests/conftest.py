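import pytest

import clonalevo as ce


@pytest.fixture()
def small_sample():
    """A 5-event, 400-cell sample with realistic noise, plus its ground truth."""
    tree = ce.simulate_tree(5, seed=101)
    fractions = ce.simulate_clone_fractions(
        tree, dirichlet_alpha=10.0, wt_fraction=0.1, seed=102
    )
    true_gt, nodes = ce.genotypes_from_tree(
        tree, fractions[0], n_cells=400, seed=103, return_assignments=True
    )
    observed = ce.add_observation_noise(
        true_gt, fpr=0.01, fnr=0.06, missing_rate=0.05, seed=104
    )
    return {
        "tree": tree,
        "fractions": fractions[0],
        "true": true_gt,
        "nodes": nodes,
        "observed": observed,
    }


@pytest.fixture()
def errors_006():
    return ce.ErrorModel(fpr=0.01, fnr=0.06)


@pytest.fixture()
def quick_config():
    return ce.McmcConfig(chain_length=4000, burn_in=0.25, thinning=5,
                         n_chains=1, seed=7, model_id=2)
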