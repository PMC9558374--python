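import numpy as np
import pytest

from cybospec.core import AtomRecord, Frame, Topology, Trajectory
from cybospec.synthetic import Regime, RegimeSpec, gen_trajectory


@pytest.fixture(scope="session")
def planted_three_regime():
    """Trajectory with three planted hydrogen-bond regimes (2/1/0 donors)
    and its ground-truth frame labels."""
    spec = RegimeSpec(
        regimes=(
            Regime(hb_count=2, dwell=0.4),
            Regime(hb_count=1, dwell=0.35),
            Regime(hb_count=0, dwell=0.25),
        ),
        n_frames=120,
        seed=11,
    )
    return gen_trajectory(None, None, spec)


@pytest.fixture(scope="session")
def two_hb_trajectory():
    """Trajectory spending all frames in a two-donor regime."""
    spec = RegimeSpec(regimes=(Regime(hb_count=2, dwell=1.0),), n_frames=40, seed=2)
    return gen_trajectory(None, None, spec)


def donor_pairs(topology):
    """Solvent (H, parent O) index pairs for hydrogen-bond scans."""
    pairs = []
    for mid in topology.molecule_ids():
        idx = topology.indices(molecule_id=mid)
        if topology.atoms[idx[0]].role != "solvent":
            continue
        o_atoms = [i for i in idx if topology.atoms[i].element == "O"]
        h_atoms = [i for i in idx if topology.atoms[i].element == "H"]
        for h in h_atoms:
            if o_atoms:
                pairs.append((h, o_atoms[0]))
    return pairs


def single_site_trajectory(positions, times=None):
    """Trajectory of one solute site A plus point 'solvent' sites B, one
    frame per row of ``positions`` (list of (n_B, 3) arrays)."""
    n_b = positions[0].shape[0]
    atoms = [AtomRecord("A", "N", 0, "solute", 0.0, 1.55)]
    for i in range(n_b):
        atoms.append(AtomRecord(f"B{i}", "O", i + 1, "solvent", 0.0, 1.52))
    top = Topology(atoms)
    frames = []
    for k, pos in enumerate(positions):
        t = times[k] if times is not None else float(k)
        coords = np.vstack([np.zeros(3), pos])
        frames.append(Frame(time=t, coordinates=coords))
    return Trajectory(topology=top, frames=frames)
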