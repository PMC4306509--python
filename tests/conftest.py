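"""Shared fixtures: small synthetic sequences and one seeded study bundle."""

from __future__ import annotations

import numpy as np
import pytest

import slimpact as sp

# Synthetic stand-in for the N-terminal region of a degron-bearing protein:
# the phospho-degron hexamer DSGIHS is placed at residues 32-37 so the
# published residue numbering of the worked example applies verbatim.
_PREFIX = "MATQADLMELWQQFEQLAEKNPHVVNKVELHM"  # residues 1-31 (synthetic)
BETA_CATENIN_LIKE = _PREFIX[:31] + "DSGIHS" + "AWQQTRNALEHAIQ"


@pytest.fixture(scope="session")
def degron_class() -> sp.MotifClass:
    return sp.MotifClass(
        "DEG_SCF_TRCP1_1",
        "DEG",
        sp.normalize_pattern("DSGx{2,3}[ST]"),
        occurrence_probability=0.0003,
        raw_pattern="DSGx{2,3}[ST]",
    )


@pytest.fixture(scope="session")
def stat5_class() -> sp.MotifClass:
    return sp.MotifClass(
        "LIG_SH2_STAT5",
        "LIG",
        sp.normalize_pattern("Y[VLTFIC]xx"),
        raw_pattern="Y[VLTFIC]xx",
    )


@pytest.fixture(scope="session")
def rgd_class() -> sp.MotifClass:
    return sp.MotifClass("LIG_RGD", "LIG", "RGD")


@pytest.fixture(scope="session")
def degron_protein() -> sp.ProteinRecord:
    assert BETA_CATENIN_LIKE[31:37] == "DSGIHS"
    return sp.ProteinRecord("CTNB1_SYN", BETA_CATENIN_LIKE)


@pytest.fixture(scope="session")
def small_study() -> "sp.SyntheticStudy":
    """One full synthetic study bundle under the default study conditions."""
    return sp.generate_study(sp.SyntheticStudyConfig(seed=7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20140724)
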