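import numpy as np
import pytest

from tcrstalk.structure_model import anchor_imgt
from tcrstalk.synthetic_data import (
    GaussianTrajSpec,
    HairpinSpec,
    make_gaussian_trajectory,
    make_hairpin,
    make_table1_standin,
)

G_LOOP = "CASGDAGGGYEQYF"   # 172.10-style CASG loop
S_LOOP = "CASSDWVSYEQYF"    # AHIII 12.2-style CASS loop


@pytest.fixture(scope="session")
def g_hairpin():
    """Default glycine-stalk hairpin with a framework tyrosine."""
    struct, manifest = make_hairpin(HairpinSpec(loop_sequence=G_LOOP, name="ghp"))
    return struct, manifest


@pytest.fixture(scope="session")
def s_hairpin():
    """Serine-stalk hairpin whose side chain is built into the structure."""
    struct, manifest = make_hairpin(HairpinSpec(loop_sequence=S_LOOP, name="shp"))
    return struct, manifest


@pytest.fixture(scope="session")
def g_anchor(g_hairpin):
    struct, manifest = g_hairpin
    return anchor_imgt(struct, manifest["beta_chain"], manifest["cdr3_seq"],
                       y40_author_number=40)


@pytest.fixture(scope="session")
def s_anchor(s_hairpin):
    struct, manifest = s_hairpin
    return anchor_imgt(struct, manifest["beta_chain"], manifest["cdr3_seq"],
                       y40_author_number=40)


@pytest.fixture(scope="session")
def standin_1u3h():
    """Synthetic stand-in engineered to the published 172.10 distances."""
    return make_table1_standin("172.10", G_LOOP, 4.98, 5.28, 4.90)


@pytest.fixture(scope="session")
def gaussian_traj():
    """Seeded Gaussian ensemble with its closed-form entropy."""
    spec = GaussianTrajSpec(n_atoms=9, n_frames=1200,
                            variances=tuple(np.geomspace(0.02, 0.2, 21)), seed=11)
    ensemble, analytic = make_gaussian_trajectory(spec)
    return spec, ensemble, analytic


def rigid_transform(coords: np.ndarray, seed: int = 5) -> np.ndarray:
    """Apply a random (seeded) proper rotation + translation to (n,3) coords."""
    from scipy.spatial.transform import Rotation
    rng = np.random.default_rng(seed)
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.normal(scale=8.0, size=3)
    return coords @ R.T + t


def transform_structure(struct, seed: int = 5):
    """Deep-copied structure with one rigid transform applied to every atom."""
    from scipy.spatial.transform import Rotation
    from tcrstalk.mutator import apply_placement  # noqa: F401 (same copy idiom)
    import copy

    rng = np.random.default_rng(seed)
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.normal(scale=8.0, size=3)
    new = copy.deepcopy(struct)
    for chains in new.models:
        for ch in chains:
            for res in ch.residues:
                for atom in res.atoms:
                    atom.coord = R @ atom.coord + t
    return new
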