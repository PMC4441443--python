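"""Independent brute-force recount implementations used as oracles.

Deliberately written with plain Python loops over individual residues,
sharing no code with the package's aggregated/streaming computation.
"""

import math

from hydrotemp.amino_acids import MAX_ASA_THEORETICAL


def _residues(chains):
    for chain in chains:
        for res in chain.residues:
            yield res.aa_type, res.exposure_fraction


def contact_oracle(chains, types, q=4.0):
    c_pool = 0.0
    n_pool = 0
    w_total = 0.0
    n_total = 0
    for aa, alpha in _residues(chains):
        n_total += 1
        w_total += q * alpha
        if aa in types:
            n_pool += 1
            c_pool += q * alpha
    omega = (n_pool * q) * w_total / (q * n_total + w_total)
    return -math.log(c_pool / omega)


def surface_oracle(chains, types, cutoff=0.07):
    n_ab = n_anb = n_b = n_nb = 0
    for aa, alpha in _residues(chains):
        buried = alpha < cutoff
        if buried:
            n_b += 1
        else:
            n_nb += 1
        if aa in types:
            if buried:
                n_ab += 1
            else:
                n_anb += 1
    return math.log((n_ab / n_anb) / (n_b / n_nb))


def area_oracle(chains, types, scaled=False):
    alpha_pool = 0.0
    n_pool = 0
    alpha_total = 0.0
    n_total = 0
    max_area_weighted = 0.0
    for aa, alpha in _residues(chains):
        n_total += 1
        alpha_total += alpha
        if aa in types:
            n_pool += 1
            alpha_pool += alpha
            max_area_weighted += MAX_ASA_THEORETICAL[aa]
    value = -math.log((n_total / n_pool) * alpha_pool / alpha_total)
    if scaled:
        value *= max_area_weighted / n_pool
    return value


def parabola_normal_equations(t, y, w):
    """Solve the 3x3 weighted normal equations directly."""
    import numpy as np

    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    x = np.column_stack([t**2, t, np.ones_like(t)])
    lhs = x.T @ (w[:, None] * x)
    rhs = x.T @ (w * y)
    return np.linalg.solve(lhs, rhs)
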