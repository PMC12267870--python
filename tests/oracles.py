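"""Independent oracles used by the model tests.

Everything here is written from the density formulas directly (no calls
into the package's likelihood or sampler code paths), so agreement with
the package is a genuine two-route check.
"""

import numpy as np
from scipy import special


def gamma_toy_posterior_moments(
    y_cells,
    prior_rho1=(4.0, 1.0),
    prior_rho2=(2.0, 100.0),
    prior_theta=(10.0, 0.05),
    n_theta=400,
    n_shape=300,
    n_rate=300,
    shape_hi=25.0,
    rate_hi=0.25,
):
    """Dense-grid quadrature for a 1-participant gamma model with fixed priors.

    The model: y = theta + x, x ~ Gamma(alpha_c, beta_c) per cell c, with
    independent Gamma priors on theta and each cell's (alpha, beta).  The
    posterior factorizes given theta, so the 1 + 2C dimensional integral
    reduces to per-cell 2-D integrals on a theta grid.

    Returns dict with means and sds of theta and each cell's alpha, beta.
    """
    y_all = np.concatenate(y_cells)
    th = np.linspace(1e-3, y_all.min() - 1e-6, n_theta)
    al = np.linspace(1e-4, shape_hi, n_shape)
    be = np.linspace(1e-6, rate_hi, n_rate)
    A, B = np.meshgrid(al, be, indexing="ij")
    a1, b1 = prior_rho1
    a2, b2 = prior_rho2
    lp_ab = (a1 - 1.0) * np.log(A) - b1 * A + (a2 - 1.0) * np.log(B) - b2 * B

    def cell_grids(y):
        out = np.empty((len(th), n_shape, n_rate))
        for i, t in enumerate(th):
            d = y - t
            s1, s2, n = np.log(d).sum(), d.sum(), len(y)
            ll = n * (A * np.log(B) - special.gammaln(A)) + (A - 1.0) * s1 - B * s2
            out[i] = ll + lp_ab
        return out

    grids = [cell_grids(np.asarray(y)) for y in y_cells]
    # per-cell marginal over (alpha, beta), and moments, on the theta grid
    shifts = [g.max() for g in grids]
    I = []  # noqa: E741
    EA, EA2, EB, EB2 = [], [], [], []
    for g, s in zip(grids, shifts):
        w = np.exp(g - s)
        I.append(np.trapezoid(np.trapezoid(w, be, axis=2), al, axis=1))
        EA.append(np.trapezoid(np.trapezoid(w * A[None], be, axis=2), al, axis=1))
        EA2.append(np.trapezoid(np.trapezoid(w * A[None] ** 2, be, axis=2), al, axis=1))
        EB.append(np.trapezoid(np.trapezoid(w * B[None], be, axis=2), al, axis=1))
        EB2.append(np.trapezoid(np.trapezoid(w * B[None] ** 2, be, axis=2), al, axis=1))

    at, bt = prior_theta
    log_w_th = (at - 1.0) * np.log(th) - bt * th
    log_w_th += sum(np.log(i) for i in I)  # product of cell marginals
    w_th = np.exp(log_w_th - log_w_th.max())
    Z = np.trapezoid(w_th, th)

    out = {
        "theta_mean": float(np.trapezoid(th * w_th, th) / Z),
        "theta_sd": 0.0,
    }
    out["theta_sd"] = float(
        np.sqrt(np.trapezoid(th**2 * w_th, th) / Z - out["theta_mean"] ** 2)
    )
    for c in range(len(y_cells)):
        for name, num, num2 in (("alpha", EA, EA2), ("beta", EB, EB2)):
            m = float(np.trapezoid(w_th / I[c] * num[c], th) / Z)
            m2 = float(np.trapezoid(w_th / I[c] * num2[c], th) / Z)
            out[f"{name}{c + 1}_mean"] = m
            out[f"{name}{c + 1}_sd"] = float(np.sqrt(max(m2 - m * m, 0.0)))
    return out


def logmeanexp_longdouble(ll_matrix):
    """Brute-force log-mean-exp over draws at extended precision."""
    x = np.asarray(ll_matrix, dtype=np.longdouble)
    m = x.max(axis=0)
    with np.errstate(divide="ignore"):
        out = m + np.log(np.exp(x - m).mean(axis=0))
    return np.asarray(out, dtype=float)


def hierarchy_prior_draws(prior_ab, lengths, n_cells_per_length, n_participants, n, rng):
    """Forward-simulate the prior of the full hierarchy (independent route).

    prior_ab: mapping name -> (a, b) as in PriorConfig.
    Returns dict of arrays: theta (n, J), rho1/rho2 (n, C), psi columns.
    """
    J, L = n_participants, len(lengths)
    C = n_cells_per_length * L
    psi = {}
    for name, (a, b) in prior_ab.items():
        psi[name] = rng.gamma(a, 1.0 / b, size=n)
    theta = rng.gamma(psi["alpha_theta"][:, None], 1.0 / psi["beta_theta"][:, None], size=(n, J))
    rho1 = np.empty((n, C))
    rho2 = np.empty((n, C))
    for li, l in enumerate(lengths):
        cols = slice(li * n_cells_per_length, (li + 1) * n_cells_per_length)
        rho1[:, cols] = rng.gamma(
            psi[f"alpha1[{l}]"][:, None], 1.0 / psi[f"beta1[{l}]"][:, None], size=(n, n_cells_per_length)
        )
        rho2[:, cols] = rng.gamma(
            psi[f"alpha2[{l}]"][:, None], 1.0 / psi[f"beta2[{l}]"][:, None], size=(n, n_cells_per_length)
        )
    return {"theta": theta, "rho1": rho1, "rho2": rho2, "psi": psi}
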