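"""Shared finite-difference gradient checker for network tests."""

import numpy as np


def finite_diff_max_err(params, loss_fn, rng, n_probe=3, h=1e-5):
    """Max relative error between analytic and central-difference gradients.

    The relative error is floored at a 1e-4 magnitude scale so that entries
    whose true gradient is dominated by finite-difference noise do not
    register as spurious failures.
    """
    loss = loss_fn()
    for p in params:
        p.grad = None
    loss.backward()
    worst = 0.0
    for p in params:
        flat, g = p.data.ravel(), p.grad.ravel()
        idx = rng.choice(flat.size, size=min(n_probe, flat.size), replace=False)
        for i in idx:
            old = flat[i]
            flat[i] = old + h
            lp = float(loss_fn().data)
            flat[i] = old - h
            lm = float(loss_fn().data)
            flat[i] = old
            num = (lp - lm) / (2.0 * h)
            ana = g[i]
            worst = max(worst, abs(num - ana) / max(abs(num), abs(ana), 1e-4))
    return worst
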