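"""Independent brute-force oracles for the map and selection operations.

Deliberately written as explicit python loops / full sorts, independent of
the vectorised implementations they check.
"""

import numpy as np


def sort_oracle(values, mode, n):
    idx = np.arange(len(values))
    if mode == "top_amplitude":
        order = sorted(idx, key=lambda i: (-values[i], i))
    elif mode == "bottom_amplitude":
        order = sorted(idx, key=lambda i: (values[i], i))
    else:
        order = sorted(idx, key=lambda i: (-abs(values[i]), i))
    return np.sort(order[:n])


def loop_wasm(X, w, idx):
    out = np.zeros(X.shape[0])
    for t in idx:
        out += w[t] * X[:, t]
    return out / len(idx)


def loop_asm(X, w, idx):
    out = np.zeros(X.shape[0])
    for t in idx:
        out += np.sign(w[t]) * X[:, t]
    return out / len(idx)


def loop_fcm(X, w, idx):
    out = np.zeros(X.shape[0])
    ws = w[idx]
    for v in range(X.shape[0]):
        xs = X[v, idx]
        num = np.sum((xs - xs.mean()) * (ws - ws.mean()))
        den = np.sqrt(np.sum((xs - xs.mean()) ** 2) * np.sum((ws - ws.mean()) ** 2))
        out[v] = num / den if den > 0 else 0.0
    return out
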