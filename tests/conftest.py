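import numpy as np
import pytest

from mesohydra.hbond import Frame


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_water(o_pos, h1_offset, h2_offset):
    """Atom rows (positions, roles) for one water molecule."""
    o = np.asarray(o_pos, dtype=float)
    return [o, o + np.asarray(h1_offset), o + np.asarray(h2_offset)], \
           ["water_O", "water_H", "water_H"]


def build_frame(waters, box=(5.0, 5.0, 5.0), lipids=(), temperature=298.0,
                z_mid=None):
    """Assemble a Frame from water O positions + H offsets and lipid sites.

    ``waters``: list of (O_pos, H1_offset, H2_offset).
    ``lipids``: list of (pos, role) for lipid heavy/H atoms, one molecule
    per consecutive (heavy, H...) run started by a heavy atom.
    """
    positions, roles, molecule = [], [], []
    mol = 0
    for o_pos, h1, h2 in waters:
        rows, rroles = make_water(o_pos, h1, h2)
        positions.extend(rows)
        roles.extend(rroles)
        molecule.extend([mol] * 3)
        mol += 1
    for pos, role in lipids:
        if role in ("lipid_donor_heavy", "lipid_acceptor_heavy"):
            mol += 1
        positions.append(np.asarray(pos, dtype=float))
        roles.append(role)
        molecule.append(mol)
    return Frame(positions=np.array(positions), roles=np.array(roles),
                 molecule=np.array(molecule), box=np.asarray(box, dtype=float),
                 temperature=temperature, z_mid=z_mid)


def random_water_frame(rng, n_water=60, box=2.0, n_lipid_sites=0):
    """Waters at random positions (random O-H geometry) in a periodic cube."""
    waters = []
    for _ in range(n_water):
        o = rng.uniform(0.0, box, 3)
        h1 = 0.1 * _random_unit(rng)
        h2 = 0.1 * _random_unit(rng)
        waters.append((o, h1, h2))
    lipids = []
    for _ in range(n_lipid_sites):
        p = rng.uniform(0.0, box, 3)
        lipids.append((p, "lipid_donor_heavy"))
        lipids.append((p + 0.1 * _random_unit(rng), "lipid_H"))
    return build_frame(waters, box=(box, box, box), lipids=lipids)


def _random_unit(rng):
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)
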