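"""Independent brute-force reference implementations used by the test suite."""

import numpy as np


def brute_force_adjust(p, method):
    """Loop-level step-down/step-up reference for the six linear adjustments."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ps = p[order]
    adj = np.empty(m)
    if method == "bonferroni":
        adj = np.array([min(1.0, m * v) for v in ps])
    elif method == "sidak":
        adj = np.array([1.0 - (1.0 - v) ** m for v in ps])
    elif method == "holm":
        running = 0.0
        for i in range(m):
            running = max(running, (m - i) * ps[i])
            adj[i] = min(running, 1.0)
    elif method == "hochberg":
        running = np.inf
        for i in range(m - 1, -1, -1):
            running = min(running, (m - i) * ps[i])
            adj[i] = min(running, 1.0)
    elif method == "bh":
        running = np.inf
        for i in range(m - 1, -1, -1):
            running = min(running, m / (i + 1) * ps[i])
            adj[i] = min(running, 1.0)
    elif method == "by":
        c = sum(1.0 / k for k in range(1, m + 1))
        running = np.inf
        for i in range(m - 1, -1, -1):
            running = min(running, c * m / (i + 1) * ps[i])
            adj[i] = min(running, 1.0)
    else:
        raise ValueError(method)
    # ties share the value at the latest tied rank
    if len(np.unique(ps)) < m:
        for i in range(m):
            adj[i] = adj[np.where(ps == ps[i])[0].max()]
    out = np.empty(m)
    out[order] = adj
    return out
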