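import pytest

from diadtox.synthdata import (
    GeneratorConfig,
    PlantSpec,
    PLANT_LIBRARY,
    generate,
    paperlike_fixture,
    plant_scheme,
)


@pytest.fixture(scope="session")
def study_shaped_set():
    """148+450 synthetic set with three plants and a PR-0.5 decoy."""
    dataset, config = paperlike_fixture(seed=1)
    return dataset, config


@pytest.fixture(scope="session")
def small_planted_set():
    """120-molecule two-class set with one fragment planted at PR 0.9."""
    config = GeneratorConfig(
        n_pos=60,
        n_neg=60,
        plants=(PlantSpec("nitrofuran", *PLANT_LIBRARY["nitrofuran"], 0.9, 20),),
        seed=7,
    )
    return generate(config), config


@pytest.fixture(scope="session")
def separable_set():
    """Set whose planted motif occurs in every positive and no negative.

    The dictionary is redundant the way real substructure dictionaries are:
    it holds the planted motif and a sub-pattern of it (both label-identical
    bits here), a correlated-but-imperfect fragment, and generic background
    patterns.
    """
    from diadtox.fingerprints import make_dictionary_provider
    from diadtox.synthdata import _BACKGROUND_SMARTS

    config = GeneratorConfig(
        n_pos=100,
        n_neg=100,
        plants=(PlantSpec("phenothiazine", *PLANT_LIBRARY["phenothiazine"], 1.0, 100),),
        seed=11,
    )
    dataset = generate(config)
    smarts = [PLANT_LIBRARY["phenothiazine"][1],  # the motif itself
              "[#7]c1ccccc1[#16]",                # its N/S-adjacent sub-pattern
              "Nc1ccccc1"] + _BACKGROUND_SMARTS   # arylamine: correlated only
    provider = make_dictionary_provider("SEP", smarts)
    return dataset, config, provider
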