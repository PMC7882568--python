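"""Small shared numerics: the repo-wide percentile convention and seed derivation."""

from __future__ import annotations

import numpy as np


def percentile(values, q):
    """Empirical percentile with linear interpolation between closest ranks.

    This single convention is used everywhere a percentile appears: spending
    winsorization, outcome-score capping, and bootstrap confidence bounds.

    Parameters
    ----------
    values : array-like
        Finite values. NaNs are ignored.
    q : float or sequence of float
        Percentile(s) in [0, 100].
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("percentile of an all-missing input is undefined")
    return np.percentile(arr, q, method="linear")


def spawn_seed(master_seed: int, stream: int) -> int:
    """Derive an independent child seed (< 2**31) from a master seed.

    Used to give each game type / replicate its own reproducible stream.
    """
    ss = np.random.SeedSequence([int(master_seed), int(stream)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
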