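"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths: prominence is
recomputed by explicit threshold descent with scipy connected-component
labelling, and RMSD by a direct one-line formula.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

_ST8 = np.ones((3, 3), dtype=bool)


def prominence_maxima(img, tolerance):
    """All local-maximum plateaus with prominence > tolerance.

    Prominence of a plateau at height v is v minus the highest threshold t at
    which the connected component of {pixels >= t} containing it also contains
    a dominating pixel: any strictly higher pixel, or an equal-valued pixel of
    a different plateau with a smaller minimum flat index (the deterministic
    tie-break).  Peaks never dominated are measured against the image minimum.
    Returns a sorted list of ((row, col) plateau centroid, peak value,
    prominence).
    """
    img = np.asarray(img, dtype=float)
    nr, nc = img.shape

    plateaus = []  # (value, min flat index, boolean mask)
    seen = np.zeros(img.shape, dtype=bool)
    for r in range(nr):
        for c in range(nc):
            if seen[r, c]:
                continue
            v = img[r, c]
            lab, _ = ndimage.label(img == v, structure=_ST8)
            comp = lab == lab[r, c]
            seen |= comp
            halo = ndimage.binary_dilation(comp, structure=_ST8) & ~comp
            if np.any(img[halo] > v):
                continue
            plateaus.append((v, int(np.flatnonzero(comp.ravel()).min()), comp))

    saddle = {i: None for i in range(len(plateaus))}
    for t in np.unique(img)[::-1]:
        lab, _ = ndimage.label(img >= t, structure=_ST8)
        for i, (v, mi, comp) in enumerate(plateaus):
            if saddle[i] is not None or t > v:
                continue
            mycomp = lab == lab[np.unravel_index(mi, img.shape)]
            if np.any(img[mycomp] > v):
                saddle[i] = t
                continue
            eq = mycomp & (img == v) & ~comp
            if eq.any() and np.flatnonzero(eq.ravel()).min() < mi:
                saddle[i] = t

    out = []
    vmin = img.min()
    for i, (v, mi, comp) in enumerate(plateaus):
        prom = v - (saddle[i] if saddle[i] is not None else vmin)
        if prom > tolerance:
            rows, cols = np.nonzero(comp)
            out.append(((int(round(rows.mean())), int(round(cols.mean()))), float(v), float(prom)))
    return sorted(out)


def rmsd_direct(y, t, slope, intercept, idx):
    """One-line RMSD of y about the line slope*t + intercept over idx."""
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    idx = np.asarray(idx, dtype=int)
    return float(np.sqrt(np.mean((y[idx] - (slope * t[idx] + intercept)) ** 2)))
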