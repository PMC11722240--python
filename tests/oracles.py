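"""Independent reference implementations used only to check the package.

These deliberately share no code with notchdyn's implementation paths:
a fixed-step RK4 integrator for the circuit ODEs, a fine-grid search for the
mixture decision boundary, a brute-force two-sample ECDF sup-distance, and a
plain moving average.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm


def rk4_circuit(kn, kd, init_notch, init_delta, topology, t_end, dt=1e-4,
                v=1.0, r=2, h=2, neighbor_input="mean", sample_every=100):
    """Fixed-step RK4 for the lateral-inhibition equations.

    Returns (times, notch, delta) sampled every ``sample_every`` steps
    (including the final step).
    """
    reduce = np.mean if neighbor_input == "mean" else np.sum
    nb = [list(x) for x in topology]

    def f(y):
        n_cells = len(nb)
        notch, delta = y[:n_cells], y[n_cells:]
        dbar = np.array([reduce(delta[ix]) for ix in nb])
        dn = dbar**r / (kn**r + dbar**r) - notch
        dd = v * (1.0 / (1.0 + (notch / kd) ** h) - delta)
        return np.concatenate([dn, dd])

    y = np.concatenate([np.asarray(init_notch, float), np.asarray(init_delta, float)])
    n_steps = int(round(t_end / dt))
    times, states = [0.0], [y.copy()]
    for step in range(1, n_steps + 1):
        k1 = f(y)
        k2 = f(y + 0.5 * dt * k1)
        k3 = f(y + 0.5 * dt * k2)
        k4 = f(y + dt * k3)
        y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if step % sample_every == 0 or step == n_steps:
            times.append(step * dt)
            states.append(y.copy())
    states = np.array(states)
    n_cells = len(nb)
    return np.array(times), states[:, :n_cells], states[:, n_cells:]


def grid_search_boundary(weights, means, sds, step=1e-5):
    """Posterior crossing point located by exhaustive fine-grid search."""
    xs = np.arange(means[0], means[1] + step, step)
    diff = (
        np.log(weights[0]) + norm.logpdf(xs, means[0], sds[0])
        - np.log(weights[1]) - norm.logpdf(xs, means[1], sds[1])
    )
    sign_change = np.nonzero(np.diff(np.sign(diff)) != 0)[0]
    assert sign_change.size >= 1, "no posterior crossing on the grid"
    i = sign_change[0]
    return 0.5 * (xs[i] + xs[i + 1])


def brute_force_ks_d(a, b):
    """sup |ECDF_a - ECDF_b| evaluated at every pooled point."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    d = 0.0
    for x in pooled:
        d = max(d, abs(np.mean(a <= x) - np.mean(b <= x)))
    return d


def moving_average_ref(values, window=5):
    """Centered moving average, edges truncated."""
    values = np.asarray(values, float)
    half = window // 2
    return np.array(
        [values[max(0, i - half): i + half + 1].mean() for i in range(len(values))]
    )
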