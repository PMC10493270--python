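"""International 10-20 montage: channel names, unit-sphere coordinates, default graph edges.

The 18-channel acquisition montage includes the earlobe references A1/A2;
the 16 scalp channels remain after average referencing and form the nodes
of the electrode graph.
"""

from __future__ import annotations

import numpy as np

#: Acquisition montage (ordered).
MONTAGE_18: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4",
    "O1", "O2", "F7", "F8", "T3", "T4", "T5", "T6", "A1", "A2",
)

#: Scalp channels retained after average referencing (A1/A2 dropped).
SCALP_16: tuple[str, ...] = MONTAGE_18[:16]

#: Alternative 10-10 names mapped onto the classic 10-20 labels used here.
CHANNEL_ALIASES: dict[str, str] = {"T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6"}

# Approximate unit-sphere positions (x: left->right, y: back->front, z: up).
# Schematic 10-20 geometry; adjacent grid positions are ~36 degrees apart.
ELECTRODE_COORDS: dict[str, np.ndarray] = {
    "Fp1": np.array([-0.309, 0.951, 0.000]),
    "Fp2": np.array([0.309, 0.951, 0.000]),
    "F7": np.array([-0.809, 0.588, 0.000]),
    "F8": np.array([0.809, 0.588, 0.000]),
    "F3": np.array([-0.545, 0.673, 0.500]),
    "F4": np.array([0.545, 0.673, 0.500]),
    "T3": np.array([-1.000, 0.000, 0.000]),
    "T4": np.array([1.000, 0.000, 0.000]),
    "C3": np.array([-0.707, 0.000, 0.707]),
    "C4": np.array([0.707, 0.000, 0.707]),
    "T5": np.array([-0.809, -0.588, 0.000]),
    "T6": np.array([0.809, -0.588, 0.000]),
    "P3": np.array([-0.545, -0.673, 0.500]),
    "P4": np.array([0.545, -0.673, 0.500]),
    "O1": np.array([-0.309, -0.951, 0.000]),
    "O2": np.array([0.309, -0.951, 0.000]),
    "A1": np.array([-0.950, 0.000, -0.312]),
    "A2": np.array([0.950, 0.000, -0.312]),
}


def canonical_name(name: str) -> str:
    """Map 10-10 style aliases (T7, P8, ...) onto the montage's 10-20 labels."""
    name = name.strip()
    return CHANNEL_ALIASES.get(name, name)


def geodesic_deg(a: str, b: str) -> float:
    """Great-circle angle (degrees) between two electrodes on the unit sphere."""
    va, vb = ELECTRODE_COORDS[a], ELECTRODE_COORDS[b]
    cos = float(np.clip(np.dot(va, vb) / (np.linalg.norm(va) * np.linalg.norm(vb)), -1.0, 1.0))
    return float(np.degrees(np.arccos(cos)))


def default_edges(threshold_deg: float = 46.0,
                  nodes: tuple[str, ...] = SCALP_16) -> list[tuple[str, str]]:
    """Edge list connecting electrodes closer than ``threshold_deg`` geodesic degrees.

    The default threshold links each 10-20 grid position to its immediate
    spatial neighbours and gives every scalp node degree >= 2.
    """
    edges = []
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            if geodesic_deg(a, b) <= threshold_deg:
                edges.append((a, b))
    return edges


def load_edge_file(path) -> list[tuple[str, str]]:
    """Read a two-column plain-text edge list (electrode-name pairs)."""
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise ValueError(f"expected two electrode names per line, got: {line!r}")
            edges.append((canonical_name(parts[0]), canonical_name(parts[1])))
    return edges
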