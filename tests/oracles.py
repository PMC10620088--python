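"""Independent brute-force oracles shared by unit and acceptance tests.

These deliberately use a different code path (scipy.ndimage labelling,
explicit Python loops) from the package implementation they check.
"""

import numpy as np
from scipy import ndimage


def tfce_bruteforce(stat, E=0.5, H=2.0, n_steps=100, conn=26):
    """Threshold-summation TFCE with explicit connected-component labelling."""
    stat = np.asarray(stat, float)
    out = np.zeros_like(stat)
    vmax = np.abs(stat).max()
    if vmax == 0:
        return out
    dh = vmax / n_steps
    struct = (np.ones((3, 3, 3)) if conn == 26
              else ndimage.generate_binary_structure(3, 1))
    for sign in (1, -1):
        s = np.maximum(sign * stat, 0.0)
        mx = s.max()
        acc = np.zeros_like(s)
        k = 1
        while k * dh <= mx + 1e-12:
            h = k * dh
            # same 1e-9 relative threshold guard as the implementation (the
            # map maximum otherwise sits exactly on the top threshold)
            labels, n_lab = ndimage.label(s >= h * (1.0 - 1e-9),
                                          structure=struct)
            for lab in range(1, n_lab + 1):
                m = labels == lab
                acc[m] += m.sum() ** E * h ** H * dh
            k += 1
        out += sign * acc
    return out
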