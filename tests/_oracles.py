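"""Independent reference computations used by multiple test modules."""

import numpy as np
import pandas as pd
from scipy.stats import rankdata


def exhaustive_pfp(fc: pd.DataFrame, direction: str) -> np.ndarray:
    """Exact pfp under the label-shuffling null, computed independently.

    Shuffling gene labels within each comparison column makes a single
    gene's per-column ranks independent uniform draws from that column's
    rank multiset; by linearity of expectation the expected count of
    permuted rank products at or below a threshold is
    G * P(geometric mean of one draw per column <= threshold), which is
    enumerated exactly over the Cartesian product of the rank multisets.
    """
    import itertools

    arr = fc.to_numpy(dtype=float)
    signed = -arr if direction == "up" else arr
    G, k = arr.shape
    cols = [rankdata(signed[:, j], method="average") for j in range(k)]
    obs_rp = np.exp(np.mean(np.log(np.column_stack(cols)), axis=1))
    products = np.array([
        float(np.prod(combo)) for combo in itertools.product(*cols)
    ])
    rp_all = products ** (1.0 / k)
    expected = np.array([
        G * np.mean(rp_all <= rp + 1e-12) for rp in obs_rp
    ])
    order = np.argsort(obs_rp, kind="stable")
    position = np.empty(G, dtype=int)
    position[order] = np.arange(1, G + 1)
    pfp = expected / position
    mono = np.empty_like(pfp)
    mono[order] = np.maximum.accumulate(pfp[order])
    return np.clip(mono, 0.0, 1.0)
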