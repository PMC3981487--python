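"""Brute-force reference implementations used only to check the library.

These deliberately avoid scipy.ndimage so that the morphology module is
checked against an independent route: dilation/erosion by explicit offset
shifting, connectivity by breadth-first flood fill, and distances by
exhaustive nearest-background search.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def shift(m: np.ndarray, off) -> np.ndarray:
    """Shift a boolean array by an integer offset, filling with False."""
    out = np.zeros_like(m)
    src = []
    dst = []
    for o, n in zip(off, m.shape):
        o = int(o)
        if abs(o) >= n:
            return out
        src.append(slice(max(-o, 0), n - max(o, 0)))
        dst.append(slice(max(o, 0), n + min(o, 0)))
    out[tuple(dst)] = m[tuple(src)]
    return out


def naive_dilate(m: np.ndarray, offsets) -> np.ndarray:
    out = np.zeros_like(m)
    for off in offsets:
        out |= shift(m, off)
    return out


def naive_erode(m: np.ndarray, offsets) -> np.ndarray:
    # outside the volume counts as background
    out = np.ones_like(m)
    for off in offsets:
        out &= shift(m, -np.asarray(off))
    # offsets reaching outside must see background -> handled by shift's False fill
    return out & m


def naive_close(m: np.ndarray, offsets) -> np.ndarray:
    return naive_erode(naive_dilate(m, offsets), offsets)


def _neighbors(connectivity: int):
    if connectivity == 6:
        return [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    offs = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    return offs


def flood_components(m: np.ndarray, connectivity: int = 6) -> list[np.ndarray]:
    """Connected components by BFS, sorted (size desc, first C-order index asc)."""
    neigh = _neighbors(connectivity)
    seen = np.zeros_like(m)
    comps = []
    for start in np.argwhere(m):
        start = tuple(start)
        if seen[start]:
            continue
        comp = np.zeros_like(m)
        q = deque([start])
        seen[start] = comp[start] = True
        while q:
            p = q.popleft()
            for off in neigh:
                np_ = tuple(p[i] + off[i] for i in range(3))
                if all(0 <= np_[i] < m.shape[i] for i in range(3)) and m[np_] and not seen[np_]:
                    seen[np_] = comp[np_] = True
                    q.append(np_)
        comps.append(comp)
    first = [int(np.flatnonzero(c.ravel())[0]) for c in comps]
    order = sorted(range(len(comps)), key=lambda i: (-int(comps[i].sum()), first[i]))
    return [comps[i] for i in order]


def flood_fill_holes(m: np.ndarray) -> np.ndarray:
    """Fill background not reachable from the border by a 6-connected flood."""
    bg = ~m
    reach = np.zeros_like(m)
    q = deque()
    for p in np.argwhere(bg):
        p = tuple(p)
        if any(p[i] in (0, m.shape[i] - 1) for i in range(3)) and not reach[p]:
            reach[p] = True
            q.append(p)
    while q:
        p = q.popleft()
        for off in _neighbors(6):
            np_ = tuple(p[i] + off[i] for i in range(3))
            if all(0 <= np_[i] < m.shape[i] for i in range(3)) and bg[np_] and not reach[np_]:
                reach[np_] = True
                q.append(np_)
    return m | (bg & ~reach)


def exhaustive_boundary_distance(m: np.ndarray) -> np.ndarray:
    """Per-voxel distance to the nearest background voxel, with a virtual
    background shell one voxel outside the volume."""
    padded = np.pad(m, 1, constant_values=False)
    bg = np.argwhere(~padded)
    out = np.zeros(m.shape, dtype=float)
    for p in np.argwhere(m):
        d2 = ((bg - (p + 1)) ** 2).sum(axis=1)
        out[tuple(p)] = np.sqrt(d2.min())
    return out
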