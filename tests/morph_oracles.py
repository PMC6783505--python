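"""Brute-force oracles shared by the morphology and acceptance tests.

These deliberately avoid scipy.ndimage: dilation/erosion are computed by
shift-accumulate over explicit offset lists, and cluster labelling by a
breadth-first flood fill, so they are independent of the implementations
they check.
"""

from collections import deque

import numpy as np


def oracle_dilate(values: np.ndarray, se) -> np.ndarray:
    r = se.radius
    pad = np.pad(values, r, constant_values=False)
    out = np.zeros_like(values)
    nx, ny, nz = values.shape
    for (ox, oy, oz) in se.offsets:
        out |= pad[r + ox:r + ox + nx, r + oy:r + oy + ny, r + oz:r + oz + nz]
    return out


def oracle_erode(values: np.ndarray, se) -> np.ndarray:
    r = se.radius
    pad = np.pad(values, r, constant_values=False)
    out = np.ones_like(values)
    nx, ny, nz = values.shape
    for (ox, oy, oz) in se.offsets:
        out &= pad[r + ox:r + ox + nx, r + oy:r + oy + ny, r + oz:r + oz + nz]
    return out


def bfs_label(binary: np.ndarray, connectivity: int) -> np.ndarray:
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                rank = abs(dx) + abs(dy) + abs(dz)
                if (connectivity == 6 and rank == 1) or \
                   (connectivity == 18 and rank <= 2) or connectivity == 26:
                    offsets.append((dx, dy, dz))
    labels = np.zeros(binary.shape, int)
    nxt = 0
    for start in np.argwhere(binary):
        s = tuple(start)
        if labels[s]:
            continue
        nxt += 1
        queue = deque([s])
        labels[s] = nxt
        while queue:
            x, y, z = queue.popleft()
            for dx, dy, dz in offsets:
                p = (x + dx, y + dy, z + dz)
                if all(0 <= p[i] < binary.shape[i] for i in range(3)) \
                        and binary[p] and not labels[p]:
                    labels[p] = nxt
                    queue.append(p)
    return labels
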