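import itertools

import pytest

from transomics import (
    SyntheticSpec,
    cross_layer_screen,
    find_triads,
    generate_dataset,
    mediation_profile,
)

LAYERS = ("lipidomics", "transcriptomics", "proteomics")


@pytest.fixture(scope="session")
def small_cohort():
    """6-sample mediated cohort with a withheld-sample factor and an outlier."""
    spec = SyntheticSpec(
        seed=11,
        group_shift=-1.0,
        missing_pattern={"lipid_002": ("S03", "C03")},
        outlier=("gene_003", "C02", 20.0),
    )
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    return small_cohort.harmonized()


@pytest.fixture(scope="session")
def large_mediated():
    """n = 1000 mediated cohort: loadings are recoverable to ~2 decimals."""
    return generate_dataset(SyntheticSpec(n_scz=500, n_con=500, seed=5))


@pytest.fixture(scope="session")
def large_dataset(large_mediated):
    return large_mediated.harmonized()


def run_screens(dataset, alpha=0.01):
    return [cross_layer_screen(dataset, a, b, alpha=alpha)
            for a, b in itertools.combinations(LAYERS, 2)]


def recover_triads(dataset, alpha=0.01):
    screens = run_screens(dataset, alpha=alpha)
    return [mediation_profile(dataset, t) for t in find_triads(screens)]


def planted_triad_positions(truth):
    """Map each planted role (x/y/z of the generator) to its position in a
    lexicographically ordered triad, using only the truth record."""
    roles = {role: truth["planted"][role]["layer"] for role in ("x", "y", "z")}
    order = sorted(roles.values())
    return {role: "xyz"[order.index(layer)] for role, layer in roles.items()}
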