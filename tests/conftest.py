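"""Shared fixtures: small synthetic studies generated at session scope."""

import pytest

from allocomp import SyntheticConfig, generate_study


@pytest.fixture(scope="session")
def small_study():
    """A small shifted study with duplicates and a panel artifact injected."""
    cfg = SyntheticConfig(
        seed=123,
        n_families_allo=6,
        n_families_comp=5,
        n_ligands_allo=80,
        n_ligands_comp=60,
        duplicate_rate=0.2,
        panel_artifact=(3, 150),
    )
    return generate_study(cfg)


@pytest.fixture(scope="session")
def null_study():
    """A no-shift study: both sets drawn from the same grammar."""
    cfg = SyntheticConfig.null(
        seed=321,
        n_families_allo=5,
        n_families_comp=5,
        n_ligands_allo=60,
        n_ligands_comp=60,
    )
    return generate_study(cfg)
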