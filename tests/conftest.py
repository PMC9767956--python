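import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


TINY_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  N   ALA A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      6  CA  ALA A   2       3.988   2.839   0.000  1.00  0.00           C
ATOM      7  CB  ALA A   2       3.539   3.663   1.204  1.00  0.00           C
ATOM      8  C   ALA A   2       5.511   2.693   0.000  1.00  0.00           C
ATOM      9  O   ALA A   2       6.029   1.577   0.000  1.00  0.00           O
ATOM     10  N   LYS A   3       6.196   3.824   0.000  1.00  0.00           N
ATOM     11  CA  LYS A   3       7.655   3.824   0.000  1.00  0.00           C
ATOM     12  C   LYS A   3       8.207   5.247   0.000  1.00  0.00           C
ATOM     13  O   LYS A   3       7.455   6.221   0.000  1.00  0.00           O
TER
END
"""

ALTLOC_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA AGLY A   1       1.458   0.000   0.000  0.60  0.00           C
ATOM      3  CA BGLY A   1       1.600   0.500   0.000  0.40  0.00           C
ATOM      4  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C
TER
END
"""

MSE_PDB = """\
HETATM    1  N   MSE A   1       0.000   0.000   0.000  1.00  0.00           N
HETATM    2  CA  MSE A   1       1.458   0.000   0.000  1.00  0.00           C
HETATM    3 SE   MSE A   1       2.500   1.500   0.000  1.00  0.00          SE
TER
END
"""

TWO_CHAIN_PDB = """\
ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY B   1      10.000   0.000   0.000  1.00  0.00           C
TER
END
"""

WATER_ONLY_PDB = """\
HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O
END
"""


@pytest.fixture
def tiny_pdb(tmp_path):
    p = tmp_path / "tiny.pdb"
    p.write_text(TINY_PDB)
    return p


@pytest.fixture
def altloc_pdb(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(ALTLOC_PDB)
    return p


@pytest.fixture
def mse_pdb(tmp_path):
    p = tmp_path / "mse.pdb"
    p.write_text(MSE_PDB)
    return p


@pytest.fixture
def two_chain_pdb(tmp_path):
    p = tmp_path / "two_chain.pdb"
    p.write_text(TWO_CHAIN_PDB)
    return p


@pytest.fixture(scope="session")
def toy_bundle():
    """Toy ring tetramer with brute-force ground-truth mask."""
    from resurf.simulate import ToyAssemblySpec, make_toy_tetramer

    spec = ToyAssemblySpec(seed=1, active_site_positions=(1,))
    model, truth, meta = make_toy_tetramer(spec)
    return spec, model, truth


@pytest.fixture(scope="session")
def toy_rsasa(toy_bundle):
    from resurf.sasa import shrake_rupley_sasa, relative_sasa
    from resurf.simulate import toy_reference

    spec, model, _ = toy_bundle
    sasa = shrake_rupley_sasa(model, spec.probe_radius, spec.n_points)
    return relative_sasa(sasa, model, toy_reference(spec.probe_radius))


def surface78_mask():
    """A 326-position mask with the first 78 positions surface-exposed
    (the monomer geometry of the asparaginase study, schematically)."""
    import numpy as np
    from resurf.sasa import DesignabilityMask

    n = 326
    surface = np.zeros(n, dtype=bool)
    surface[:78] = True
    return DesignabilityMask(
        positions=list(range(1, n + 1)),
        surface=surface,
        active_site_proximal=np.zeros(n, dtype=bool),
        interface=np.zeros(n, dtype=bool),
        designable=np.ones(n, dtype=bool),
    )


@pytest.fixture
def asn_like_mask():
    return surface78_mask()
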