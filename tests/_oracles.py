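"""Deliberately naive reference implementations used only as test oracles.

Everything here is written with explicit Python loops, independent of the
vectorized code paths under test.
"""

import math


def naive_match_prob(acc, gyro, ell, n_templates, r_acc, r_gyro, match_mode):
    """Average per-template match fraction via an explicit triple loop."""
    fracs = []
    for i in range(n_templates):
        s = 0.0
        for j in range(n_templates):
            if i == j:
                continue
            d_acc = max(abs(acc[i + k] - acc[j + k]) for k in range(ell))
            d_gyro = max(abs(gyro[i + k] - gyro[j + k]) for k in range(ell))
            if match_mode == "literal_average":
                s += (float(d_acc <= r_acc) + float(d_gyro <= r_gyro)) / 2.0
            else:
                s += float(d_acc <= r_acc and d_gyro <= r_gyro)
        fracs.append(s / (n_templates - 1))
    return sum(fracs) / len(fracs)


def naive_match_counts(
    acc, gyro, xi, r_acc, r_gyro, match_mode, normalization
):
    w = len(acc)
    n_long = w - xi
    if normalization == "sampen_consistent":
        b_xi = naive_match_prob(acc, gyro, xi, n_long, r_acc, r_gyro, match_mode)
    else:
        b_xi = naive_match_prob(
            acc, gyro, xi, w - xi + 1, r_acc, r_gyro, match_mode
        )
    b_xi1 = naive_match_prob(
        acc, gyro, xi + 1, n_long, r_acc, r_gyro, match_mode
    )
    return b_xi, b_xi1


def naive_motion_entropy(
    acc, gyro, xi, r_acc, r_gyro, match_mode, normalization
):
    b_xi, b_xi1 = naive_match_counts(
        acc, gyro, xi, r_acc, r_gyro, match_mode, normalization
    )
    if b_xi <= 0 or b_xi1 <= 0:
        return math.inf
    return -math.log(b_xi1 / b_xi)


def naive_sampen(x, m, r):
    """Textbook single-channel sample entropy (template pairs, i != j)."""
    n = len(x)

    def count(mm):
        c = 0
        for i in range(n - m):
            for j in range(n - m):
                if i == j:
                    continue
                d = max(abs(x[i + k] - x[j + k]) for k in range(mm))
                if d <= r:
                    c += 1
        return c

    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        return math.inf
    return -math.log(a / b)


def enumerate_window_starts(T, w, step):
    """0-based start offsets of the printed count formula's windows."""
    L = (T - w) // step if w <= T else 0
    return [(k - 1) * step for k in range(1, L + 1)]
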