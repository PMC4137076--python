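"""Independent oracles used by the tests.

These deliberately avoid the package's own code paths: the mixture oracle
is a plain double loop, and the posterior oracle enumerates every topic
assignment vector of a tiny corpus and averages the Rao-Blackwellised
estimates under the exact collapsed posterior.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.special import gammaln


def double_loop_mixture(theta, phi):
    """p(ph|d) = sum over topics, accumulated scalar-by-scalar."""
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    M, K = theta.shape
    N = phi.shape[1]
    out = np.zeros((M, N))
    for d in range(M):
        for w in range(N):
            s = 0.0
            for t in range(K):
                s += theta[d, t] * phi[t, w]
            out[d, w] = s
    return out


def exact_posterior_means(doc_ids, word_ids, n_docs, n_words, n_topics, alpha, beta):
    """Exact E[theta], E[phi] by enumerating all K^n assignment vectors.

    Weights are the collapsed joint p(z, w) up to a constant; expectations
    average (n_dk+a)/(n_d+Ka) and (n_kw+b)/(n_k+Vb) under those weights.
    Feasible only for a handful of tokens.
    """
    doc_ids = np.asarray(doc_ids)
    word_ids = np.asarray(word_ids)
    n = len(doc_ids)
    nd = np.bincount(doc_ids, minlength=n_docs)
    log_ws = []
    thetas = []
    phis = []
    for z in itertools.product(range(n_topics), repeat=n):
        z = np.asarray(z)
        ndk = np.zeros((n_docs, n_topics))
        nkw = np.zeros((n_topics, n_words))
        for i in range(n):
            ndk[doc_ids[i], z[i]] += 1
            nkw[z[i], word_ids[i]] += 1
        nk = nkw.sum(axis=1)
        log_w = gammaln(ndk + alpha).sum()
        log_w += gammaln(nkw + beta).sum() - gammaln(nk + n_words * beta).sum()
        log_ws.append(log_w)
        thetas.append((ndk + alpha) / (nd[:, None] + n_topics * alpha))
        phis.append((nkw + beta) / (nk[:, None] + n_words * beta))
    log_ws = np.asarray(log_ws)
    w = np.exp(log_ws - log_ws.max())
    w /= w.sum()
    theta = np.tensordot(w, np.asarray(thetas), axes=1)
    phi = np.tensordot(w, np.asarray(phis), axes=1)
    return theta, phi
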