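"""Independent brute-force oracles used only by the tests.

Each function re-derives a quantity from first principles, without calling
the package's implementation, so tests compare two independent routes.
"""

import numpy as np


def dft_band_power(trace, fs, low_hz, high_hz):
    """Band power by explicit DFT summation over one-sided bins [low, high)."""
    x = np.asarray(trace, dtype=float)
    n = len(x)
    ks = np.arange(n // 2 + 1)
    total = 0.0
    for k in ks:
        f = k * fs / n
        if not (low_hz <= f < high_hz):
            continue
        coeff = np.sum(x * np.exp(-2j * np.pi * k * np.arange(n) / n))
        p = abs(coeff) ** 2 / n**2
        if 0 < k < n / 2:  # one-sided doubling except DC and Nyquist
            p *= 2
        total += p
    return total


def katz_fd_stepwise(trace):
    """Katz fractal dimension of a waveform, evaluated point by point."""
    x = np.asarray(trace, dtype=float)
    L = 0.0
    for i in range(1, len(x)):
        L += abs(x[i] - x[i - 1])
    d = 0.0
    for i in range(1, len(x)):
        d = max(d, abs(x[i] - x[0]))
    n = len(x) - 1
    return np.log10(n) / (np.log10(n) + np.log10(d / L))


def pearson_direct(a, b):
    """Pearson correlation from the covariance / (sigma sigma) definition."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    am, bm = a - a.mean(), b - b.mean()
    return float(np.sum(am * bm) / np.sqrt(np.sum(am**2) * np.sum(bm**2)))


def auroc_pairwise(scores, labels):
    """Mann-Whitney AUROC: fraction of (pos, neg) pairs ranked correctly, ties 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def metrics_direct(tp, fp, tn, fn):
    """Precision/recall/F1/accuracy straight from the defining ratios."""
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    f1 = 2 * precision * recall / (precision + recall)
    accuracy = (tp + tn) / (tp + fp + tn + fn)
    return precision, recall, f1, accuracy
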