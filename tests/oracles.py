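"""Independent numerical oracles used by the test-suite.

These deliberately avoid the package's samplers and estimators: the
posterior oracle is dense-grid quadrature, the permutation oracle is
exhaustive enumeration.
"""

import itertools

import numpy as np
from scipy.special import expit, logsumexp

VAGUE_VAR = 1000.0
SIGMA_MAX = 100.0


def grid_posterior_mean_q(y, genet_idx, n_b=401, n_a=201, n_sig=48, span=12.0):
    """E[inv-logit(g0 + g_i) | y] for the intercept+locus+genet Bernoulli model.

    ``y`` is (L, S) binary, ``genet_idx`` (S,) ints.  Exploits that the
    likelihood only sees a_i = g0 + g_i and b_ik = a_i + g_ik:

      p(a | sig_g) = MVN(0, vague_var * J + sig_g^2 * I)   (g0 integrated out)
      M_ik(a, sig_gk) = int N(b - a; 0, sig_gk) lik_ik(b) db

    then quadrature over (sig_g, sig_gk, a_1..a_L) with log-spaced sigma
    grids under the Uniform(0, 100) prior.  Works for L = 2.
    """
    L, S = y.shape
    assert L == 2, "oracle implemented for the two-locus layout"
    G = int(genet_idx.max()) + 1
    b = np.linspace(-span, span, n_b)
    db = b[1] - b[0]
    a = np.linspace(-span, span, n_a)
    sig = np.geomspace(0.05, SIGMA_MAX, n_sig)

    # per (locus, genet) binomial log-likelihood on the b grid
    loglik = np.zeros((L, G, n_b))
    for i in range(L):
        for k in range(G):
            sel = genet_idx == k
            yk, nk = y[i, sel].sum(), sel.sum()
            loglik[i, k] = yk * np.log(expit(b)) + (nk - yk) * np.log(expit(-b))

    # log M[i, k, sig_gk, a] via quadrature over b
    diff = b[None, :] - a[:, None]  # (n_a, n_b)
    logM = np.empty((L, G, n_sig, n_a))
    for si, s in enumerate(sig):
        logW = -0.5 * (diff / s) ** 2 - np.log(s) - 0.5 * np.log(2 * np.pi)
        for i in range(L):
            for k in range(G):
                logM[i, k, si] = logsumexp(logW + loglik[i, k][None, :], axis=1) + np.log(db)
    logF = logM.sum(axis=1)  # (L, n_sig, n_a) product over genets

    # bivariate normal of (a_1, a_2) given sig_g, with g0 marginalised
    A1, A2 = np.meshgrid(a, a, indexing="ij")
    da = a[1] - a[0]
    # trapezoid weights for the sigma grids (prior constant on (0, 100))
    wsig = np.gradient(sig)

    logZ_terms = []
    num1_terms = []
    num2_terms = []
    q1 = expit(A1)
    q2 = expit(A2)
    for gi, sg in enumerate(sig):
        cov = np.array([[VAGUE_VAR + sg**2, VAGUE_VAR], [VAGUE_VAR, VAGUE_VAR + sg**2]])
        prec = np.linalg.inv(cov)
        _, logdet = np.linalg.slogdet(cov)
        logG = (
            -0.5
            * (
                prec[0, 0] * A1**2
                + 2 * prec[0, 1] * A1 * A2
                + prec[1, 1] * A2**2
            )
            - 0.5 * logdet
            - np.log(2 * np.pi)
        )
        for ki, sk in enumerate(sig):
            lg = logG + logF[0, ki][:, None] + logF[1, ki][None, :]
            w = np.log(wsig[gi]) + np.log(wsig[ki])
            logZ_terms.append(logsumexp(lg) + w)
            num1_terms.append(logsumexp(lg + np.log(q1)) + w)
            num2_terms.append(logsumexp(lg + np.log(q2)) + w)
    logZ = logsumexp(logZ_terms)
    return np.array(
        [np.exp(logsumexp(num1_terms) - logZ), np.exp(logsumexp(num2_terms) - logZ)]
    )


def exhaustive_permutation_p(C, masks, eps=1e-12):
    """Two-sided permutation p-values for r over all n! location permutations.

    Returns (p, p_strict): the tie-inclusive estimate (|r| >= |obs| - eps)
    and the tie-exclusive one (|r| > |obs| + eps).  Any tie-resolution
    convention yields a p-value between the two.
    """
    n = C.shape[0]
    obs = _r_classes(C, masks)
    count = np.zeros(len(masks))
    count_strict = np.zeros(len(masks))
    total = 0
    for perm in itertools.permutations(range(n)):
        Cp = C[np.ix_(perm, perm)]
        rp = _r_classes(Cp, masks)
        count += np.abs(rp) >= np.abs(obs) - eps
        count_strict += np.abs(rp) > np.abs(obs) + eps
        total += 1
    return count / total, count_strict / total


def _r_classes(C, masks):
    out = []
    for m in masks:
        i, j = np.nonzero(m)
        num = C[i, j].sum()
        den = 0.5 * (C[i, i] + C[j, j]).sum()
        out.append(num / den if den != 0 else np.nan)
    return np.array(out)
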