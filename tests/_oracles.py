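"""Independent brute-force reference implementations.

Deliberately naive (double loops, exhaustive scans) so they share no code
path with the package; used to pin down the fast implementations.
"""

import math

import numpy as np


def appen_bruteforce(x, m, r):
    x = np.asarray(x, dtype=float)
    n = len(x)
    tol = r * x.std()
    if x.std() == 0:
        return 0.0

    def phi(mm):
        templates = [x[i:i + mm] for i in range(n - mm + 1)]
        total = 0.0
        for a in templates:
            count = 0
            for b in templates:
                if max(abs(a - b)) <= tol:
                    count += 1
            total += math.log(count / len(templates))
        return total / len(templates)

    return phi(m) - phi(m + 1)


def sampen_bruteforce(x, m, r):
    x = np.asarray(x, dtype=float)
    n = len(x)
    if x.std() == 0:
        return 0.0
    tol = r * x.std()

    def pairs(mm):
        templates = [x[i:i + mm] for i in range(n - m)]
        count = 0
        for i in range(len(templates)):
            for j in range(i + 1, len(templates)):
                if max(abs(templates[i] - templates[j])) <= tol:
                    count += 1
        return count

    b = pairs(m)
    a = pairs(m + 1)
    if a == 0 or b == 0:
        return math.inf
    return -math.log(a / b)


def pen_bruteforce(x, order, delay):
    x = np.asarray(x, dtype=float)
    n = len(x)
    patterns = {}
    for i in range(n - (order - 1) * delay):
        window = x[i:i + (order - 1) * delay + 1:delay]
        # stable argsort: ties broken by order of appearance
        pattern = tuple(sorted(range(order), key=lambda k: (window[k], k)))
        patterns[pattern] = patterns.get(pattern, 0) + 1
    total = sum(patterns.values())
    h = -sum((c / total) * math.log(c / total) for c in patterns.values())
    return h / math.log(math.factorial(order))


def higuchi_bruteforce(x, kmax):
    x = np.asarray(x, dtype=float)
    n = len(x)
    logs = []
    for k in range(1, kmax + 1):
        lmk_values = []
        for m in range(k):
            n_steps = (n - 1 - m) // k
            if n_steps < 1:
                continue
            length = 0.0
            for i in range(1, n_steps + 1):
                length += abs(x[m + i * k] - x[m + (i - 1) * k])
            length *= (n - 1) / (n_steps * k)
            lmk_values.append(length / k)
        logs.append((math.log(1.0 / k), math.log(sum(lmk_values) / len(lmk_values))))
    xs = np.array([p[0] for p in logs])
    ys = np.array([p[1] for p in logs])
    slope = ((xs - xs.mean()) * (ys - ys.mean())).sum() / ((xs - xs.mean()) ** 2).sum()
    return slope


def winning_neuron_bruteforce(weights, x):
    best = None
    best_d = math.inf
    rows, cols, _ = weights.shape
    for i in range(rows):
        for j in range(cols):
            d = float(((weights[i, j] - x) ** 2).sum())
            if d < best_d - 1e-15:
                best_d = d
                best = (i, j)
    return best


def quantization_error_bruteforce(weights, Z):
    total = 0.0
    for row in Z:
        best = math.inf
        for i in range(weights.shape[0]):
            for j in range(weights.shape[1]):
                d = math.sqrt(float(((weights[i, j] - row) ** 2).sum()))
                best = min(best, d)
        total += best
    return total / len(Z)


def ae_mse_bruteforce(s, s_hat):
    s = np.asarray(s, dtype=float)
    s_hat = np.asarray(s_hat, dtype=float)
    total = 0.0
    count = 0
    for idx in np.ndindex(s.shape):
        total += (s[idx] - s_hat[idx]) ** 2
        count += 1
    return total / count


def despike_bruteforce(x, window, threshold_sds):
    x = np.asarray(x, dtype=float)
    n = len(x)
    half = window // 2
    med = np.empty(n)
    for i in range(n):
        lo = max(i - half, 0)
        hi = min(i + half + 1, n)
        # 'nearest' edge handling: pad by repeating edge values
        vals = list(x[lo:hi])
        vals += [x[0]] * (half - (i - lo)) + [x[-1]] * (half - (hi - 1 - i))
        med[i] = np.median(vals)
    resid = np.abs(x - med)
    scale = max(1.4826 * np.median(resid),
                np.percentile(resid, 99) / 2.576)
    out = x.copy()
    for i in range(n):
        spike = resid[i] > threshold_sds * scale if scale > 0 else resid[i] > 0
        if spike:
            out[i] = med[i]
    return out
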