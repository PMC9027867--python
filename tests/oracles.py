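"""Independent brute-force oracle for the N-mixture likelihood.

Enumerates the latent abundance N directly and sums plain scipy.stats
probability products — no log-space tricks, no shared code with the
implementation it checks.
"""

import numpy as np
from scipy import stats


def brute_force_negloglik(y, lam, p, mixture="P", psi=0.0, theta=1.0,
                          n_max=1000):
    """-log likelihood by direct enumeration of N = 0..n_max per site.

    ``y`` is an (M, J) array (NaN for missing visits), ``lam`` and ``p``
    per-site vectors.
    """
    y = np.asarray(y, dtype=float)
    n_grid = np.arange(n_max + 1)
    total = 0.0
    for i in range(y.shape[0]):
        yi = y[i][np.isfinite(y[i])]
        if mixture == "P":
            g = stats.poisson.pmf(n_grid, lam[i])
        elif mixture == "NB":
            g = stats.nbinom.pmf(n_grid, theta, theta / (theta + lam[i]))
        elif mixture == "ZIP":
            g = (1.0 - psi) * stats.poisson.pmf(n_grid, lam[i])
            g[0] += psi
        else:
            raise ValueError(mixture)
        detect = np.prod(stats.binom.pmf(yi[None, :], n_grid[:, None], p[i]),
                         axis=1)
        total += np.log(float(g @ detect))
    return -total
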