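import numpy as np
import pytest
from hypothesis import settings

from bindmodes import synthetic, trajio

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


def make_tripeptide() -> trajio.Topology:
    """ALA-ARG-ALA with explicit backbone + amide H; ARG numbered 288."""
    names, elements, resids, resnames, chains = [], [], [], [], []
    bonds = []
    spec = [
        (287, "ALA", ["N", "H", "CA", "C", "O"]),
        (288, "ARG", ["N", "H", "CA", "C", "O", "CB", "CG", "CD", "NE", "CZ",
                      "NH1", "NH2"]),
        (289, "ALA", ["N", "H", "CA", "C", "O"]),
    ]
    for resid, resname, atom_names in spec:
        base = len(names)
        for n in atom_names:
            names.append(n)
            elements.append("H" if n == "H" else n[0])
            resids.append(resid)
            resnames.append(resname)
            chains.append("A")
        bonds += [(base, base + 1), (base, base + 2), (base + 2, base + 3),
                  (base + 3, base + 4)]
        for extra in range(5, len(atom_names)):
            bonds.append((base + extra - 1 if extra > 5 else base + 2,
                          base + extra))
    return trajio.Topology(
        names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        resids=np.array(resids, dtype=int),
        resnames=np.array(resnames, dtype=object),
        chains=np.array(chains, dtype=object),
        bonds=np.array(bonds, dtype=int),
    )


@pytest.fixture(scope="session")
def tripeptide():
    return make_tripeptide()


@pytest.fixture(scope="session")
def small_system():
    """200-frame toy system with two scheduled H-bonds (in memory)."""
    spec = synthetic.SyntheticSpec(
        n_frames=200, seed=11,
        hbond_schedule={(2, 7): 60.0, (3, 9): 100.0},
    )
    traj, truth = synthetic.generate(spec)
    return spec, traj, truth


@pytest.fixture(scope="session")
def mode_system():
    """1000-frame three-mode system used for end-to-end recovery checks."""
    spec = synthetic.SyntheticSpec(n_frames=1000, seed=42)
    traj, truth = synthetic.generate(spec)
    return spec, traj, truth


@pytest.fixture()
def disk_system(tmp_path):
    """Small system written to PDB + DCD + JSON on disk."""
    spec = synthetic.SyntheticSpec(n_frames=20, seed=5,
                                   hbond_schedule={(2, 7): 50.0})
    traj, truth = synthetic.generate(spec, tmp_path)
    return tmp_path, spec, traj, truth
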