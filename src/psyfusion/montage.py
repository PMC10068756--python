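"""EEG montage geometry: channel positions, adjacency, mirror pairs.

Positions come from MNE's bundled ``standard_1020`` template montage; the
adjacency graph joins channels closer than a multiple of the median
nearest-neighbor distance, which on the default 31-channel set yields a
mean degree in the 4-6 range.  A user-supplied edge table can override the
computed graph.
"""

from __future__ import annotations

import numpy as np


def channel_positions(channel_names) -> np.ndarray:
    """2D (x, y) scalp positions for the named channels."""
    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        montage = mne.channels.make_standard_montage("standard_1020")
    pos3d = montage.get_positions()["ch_pos"]
    missing = [ch for ch in channel_names if ch not in pos3d]
    if missing:
        raise KeyError(f"channels not in standard_1020 montage: {missing}")
    return np.array([pos3d[ch][:2] for ch in channel_names])


def build_adjacency(channel_names, scale: float = 2.1) -> dict:
    """Neighbor map {index: set(indices)} from montage distances.

    Two channels are neighbors when their 2D distance is below ``scale``
    times the median nearest-neighbor distance.
    """
    pos = channel_positions(channel_names)
    n = len(channel_names)
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    threshold = scale * np.median(d.min(axis=1))
    neighbors = {i: set(np.flatnonzero(d[i] <= threshold).tolist()) for i in range(n)}
    return neighbors


def adjacency_from_edges(channel_names, edges) -> dict:
    """Neighbor map from an explicit (name, name) edge list."""
    index = {ch: i for i, ch in enumerate(channel_names)}
    neighbors = {i: set() for i in range(len(channel_names))}
    for a, b in edges:
        if a == b:
            continue
        i, j = index[a], index[b]
        neighbors[i].add(j)
        neighbors[j].add(i)
    return neighbors


def mean_degree(neighbors: dict) -> float:
    return float(np.mean([len(v) for v in neighbors.values()]))


def mirror_channel(name: str) -> str:
    """Contralateral partner of a 10-20 label (midline maps to itself).

    Odd trailing numbers are left-hemisphere, even are right; the mirror
    swaps n with n+1 (odd) or n-1 (even).
    """
    if name.endswith("z"):
        return name
    head = name.rstrip("0123456789")
    digits = name[len(head):]
    if not digits:
        return name
    n = int(digits)
    return f"{head}{n + 1 if n % 2 else n - 1}"
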