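"""Shared fixtures and independent reference implementations.

The reference solvers here are deliberately written point-by-point with
explicit loops, independent of the vectorized assembly under test.
"""

import numpy as np
import pytest

import morphogrid as mg


@pytest.fixture(scope="session")
def default_config():
    return mg.make_config()


@pytest.fixture(scope="session")
def noise_free_config():
    return mg.make_config(cv_p=0.0, cv_d=0.0, cv_D=0.0, n_realizations=2)


def dense_reference_solution(config, kin):
    """Brute-force dense solve of the five-point flux-form stencil.

    Loops over every fine-grid point, looks up its cell's kinetics, and
    couples it to each neighbor with the harmonic-mean interface
    diffusivity; zero-flux boundaries drop the coupling, periodic
    transverse boundaries wrap it.
    """
    m = config.points_per_cell
    my, mx = config.n_rows * m, config.n_cols * m
    hx, hy = config.delta_x / m, config.delta_y / m
    n = my * mx
    A = np.zeros((n, n))
    b = np.zeros(n)

    def diff(j, i):
        return kin.D[j // m, i // m]

    for j in range(my):
        for i in range(mx):
            k = j * mx + i
            r, c = j // m, i // m
            A[k, k] += kin.d[r, c]
            if c < config.n_source_cols:
                b[k] = kin.p[r, c]
            for jj, ii, h, fac in (
                (j, i - 1, hx, 1.0),
                (j, i + 1, hx, 1.0),
                (j - 1, i, hy, config.alpha),
                (j + 1, i, hy, config.alpha),
            ):
                if ii < 0 or ii >= mx:
                    continue
                if jj < 0 or jj >= my:
                    if config.bc_y == "periodic" and my > 1:
                        jj %= my
                    else:
                        continue
                d_pair = 2.0 * diff(j, i) * diff(jj, ii) / (diff(j, i) + diff(jj, ii))
                w = fac * d_pair / h**2
                A[k, k] += w
                A[k, jj * mx + ii] -= w
    return np.linalg.solve(A, b)


def brute_force_crossings(averages, threshold, delta_x, rule):
    """Enumerate threshold crossings of a step profile pair by pair."""
    crossings = []
    a = list(averages)
    if rule == "cell-boundary":
        for i in range(len(a) - 1):
            if (a[i] >= threshold) != (a[i + 1] >= threshold):
                crossings.append((i + 1) * delta_x)
    else:
        centers = [(i + 0.5) * delta_x for i in range(len(a))]
        s = [np.log(v) - np.log(threshold) for v in a]
        for i, si in enumerate(s):
            if si == 0.0:
                crossings.append(centers[i])
        for i in range(len(a) - 1):
            if s[i] * s[i + 1] < 0:
                frac = s[i] / (s[i] - s[i + 1])
                crossings.append(centers[i] + frac * (centers[i + 1] - centers[i]))
    return crossings
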