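import pytest

from biobombe import (
    SyntheticSpec,
    generate_expression,
    minmax_scale,
    stratified_split,
)


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticSpec(
        n_samples=150,
        n_genes=400,
        n_factors=3,
        genes_per_factor=25,
        factor_strength=2.0,
        noise_sd=0.5,
        n_tissues=3,
        trait_effects={0: 2.0},
        n_decoy_sets=5,
        decoy_set_size=20,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_data(small_spec):
    return generate_expression(small_spec)


@pytest.fixture(scope="session")
def small_expr(small_data):
    return small_data[0]


@pytest.fixture(scope="session")
def small_truth(small_data):
    return small_data[1]


@pytest.fixture(scope="session")
def scaled_parts(small_expr):
    pair = stratified_split(small_expr, 0.9, "tissue", seed=0)
    return minmax_scale(pair.train), minmax_scale(pair.test)
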