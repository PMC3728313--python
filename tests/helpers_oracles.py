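"""Independent numerical oracles for the test suite.

These deliberately avoid the package's simulation path: expectations for the
max of (correlated) normal pathway phenotypes are computed by Gauss-Hermite
quadrature and closed forms, and serve as cross-checks for the Monte-Carlo
estimators.
"""

import numpy as np
from scipy import stats


def gauss_hermite_2d(n_nodes: int = 80):
    """Nodes/weights for E[f(Z1, Z2)] with Z1, Z2 iid standard normal."""
    x, w = np.polynomial.hermite_e.hermegauss(n_nodes)
    w = w / np.sqrt(2.0 * np.pi)
    X1, X2 = np.meshgrid(x, x, indexing="ij")
    W = np.outer(w, w)
    return X1, X2, W


def max2_mean_var():
    """Closed-form mean and variance of max of two iid standard normals."""
    mean = 1.0 / np.sqrt(np.pi)
    var = 1.0 - 1.0 / np.pi
    return mean, var


def narrow_h2_basic_k2(h2_path: float, n_nodes: int = 80) -> float:
    """Regression-based narrow-sense h2 for the basic two-pathway model.

    Pathway phenotypes P1, P2 iid N(0,1); Y = max(P1, P2).  Since
    E[A1 | P1] = h2 * P1, Cov(Y, A1) = h2 * Cov(Y, P1) by quadrature.  With
    independent pathways the OLS coefficients are beta_j = Cov(Y, A_j) /
    Var(A_j) and the fitted genetic variance is sum_j beta_j^2 Var(A_j).
    """
    P1, P2, W = gauss_hermite_2d(n_nodes)
    Y = np.maximum(P1, P2)
    ey = np.sum(Y * W)
    var_y = np.sum(Y**2 * W) - ey**2
    cov_y_p1 = np.sum(Y * P1 * W)  # E[Y P1], P1 has mean 0
    cov_y_a1 = h2_path * cov_y_p1
    beta = cov_y_a1 / h2_path  # Var(A1) = h2_path
    fitted_var = 2.0 * beta**2 * h2_path  # symmetric pathways
    return fitted_var / var_y


def _emax_two_normals(m1, m2, s1sq, s2sq):
    """E[max(X1, X2)] for independent normals (closed form)."""
    theta = np.sqrt(s1sq + s2sq)
    d = (m1 - m2) / theta
    return m1 * stats.norm.cdf(d) + m2 * stats.norm.cdf(-d) + theta * stats.norm.pdf(d)


def shared_c_cov_basic_k2(h2_path: float, c2_path: float,
                          n_nodes: int = 80) -> float:
    """Cov(Y1, Y2)/Var(Y) for pairs sharing only common environment, k=2.

    Nested conditioning: given the shared C = (c1, c2), each sibling's
    pathway phenotypes are independent normals with means c_j and variance
    1 - varC, so E[Y | C] has a closed form; the outer expectation over C
    is Gauss-Hermite quadrature.  Var(Y) is computed the same way from
    E[Y^2] via 2-D quadrature on the full pathway distribution.
    """
    var_c = c2_path * (1.0 - h2_path)
    resid = 1.0 - var_c  # per-pathway variance given C
    Z1, Z2, W = gauss_hermite_2d(n_nodes)
    c1, c2 = np.sqrt(var_c) * Z1, np.sqrt(var_c) * Z2
    e_y_given_c = _emax_two_normals(c1, c2, resid, resid)
    ey = np.sum(e_y_given_c * W)
    cov_shared = np.sum(e_y_given_c**2 * W) - ey**2
    # full-variance quadrature over the unconditional pathway phenotypes
    P1, P2, W2 = gauss_hermite_2d(n_nodes)
    Y = np.maximum(P1, P2)
    var_y = np.sum(Y**2 * W2) - np.sum(Y * W2) ** 2
    return cov_shared / var_y
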