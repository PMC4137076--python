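"""Collapsed Gibbs sampling kernels for the topic model.

All randomness comes from an explicit xorshift64* generator seeded through
splitmix64, so a (seed, corpus, config) triple maps to bit-identical output
regardless of platform RNG details.  Counts are integer; the conditional
p(z_i = k | z_-i, w) ∝ (n_dk + α)(n_kw + β)/(n_k + Vβ) is the standard
collapsed form with θ and φ integrated out.
"""

from __future__ import annotations

import numba as nb
import numpy as np

_U64 = np.uint64


@nb.njit(nb.uint64(nb.uint64), cache=False)
def _splitmix64(seed):
    z = seed + _U64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> _U64(27))) * _U64(0x94D049BB133111EB)
    z = z ^ (z >> _U64(31))
    if z == _U64(0):
        z = _U64(0x9E3779B97F4A7C15)
    return z


@nb.njit(nb.float64(nb.uint64[:]), cache=False, inline="always")
def _uniform(state):
    # xorshift64* ; top 53 bits -> double in [0, 1)
    x = state[0]
    x ^= x >> _U64(12)
    x ^= (x << _U64(25)) & _U64(0xFFFFFFFFFFFFFFFF)
    x ^= x >> _U64(27)
    state[0] = x
    bits = (x * _U64(0x2545F4914F6CDD1D)) >> _U64(11)
    return np.float64(bits) * (1.0 / 9007199254740992.0)


@nb.njit(cache=False)
def gibbs_fit(
    doc_ids,
    word_ids,
    n_docs,
    n_words,
    n_topics,
    alpha,
    beta,
    n_iterations,
    burn_in,
    sample_lag,
    seed,
):
    """Run the collapsed sampler; return posterior-mean (theta, phi, n_samples).

    theta/phi are averages of the Rao-Blackwellised plug-in estimates
    (n_dk + α)/(n_d + Kα) and (n_kw + β)/(n_k + Vβ) over post-burn-in
    samples taken every ``sample_lag`` iterations.
    """
    n_tokens = doc_ids.shape[0]
    state = np.empty(1, np.uint64)
    state[0] = _splitmix64(np.uint64(seed))

    z = np.empty(n_tokens, np.int64)
    ndk = np.zeros((n_docs, n_topics), np.int64)
    nkw = np.zeros((n_topics, n_words), np.int64)
    nk = np.zeros(n_topics, np.int64)
    nd = np.zeros(n_docs, np.int64)
    for i in range(n_tokens):
        k = int(_uniform(state) * n_topics)
        if k >= n_topics:
            k = n_topics - 1
        z[i] = k
        ndk[doc_ids[i], k] += 1
        nkw[k, word_ids[i]] += 1
        nk[k] += 1
        nd[doc_ids[i]] += 1

    theta_sum = np.zeros((n_docs, n_topics), np.float64)
    phi_sum = np.zeros((n_topics, n_words), np.float64)
    n_samples = 0
    cum = np.empty(n_topics, np.float64)
    vbeta = n_words * beta
    for it in range(n_iterations):
        for i in range(n_tokens):
            d = doc_ids[i]
            w = word_ids[i]
            k = z[i]
            ndk[d, k] -= 1
            nkw[k, w] -= 1
            nk[k] -= 1
            total = 0.0
            for t in range(n_topics):
                total += (ndk[d, t] + alpha) * (nkw[t, w] + beta) / (nk[t] + vbeta)
                cum[t] = total
            u = _uniform(state) * total
            k = 0
            while k < n_topics - 1 and cum[k] <= u:
                k += 1
            z[i] = k
            ndk[d, k] += 1
            nkw[k, w] += 1
            nk[k] += 1
        if it >= burn_in and (it - burn_in) % sample_lag == 0:
            n_samples += 1
            for d in range(n_docs):
                denom = nd[d] + n_topics * alpha
                for t in range(n_topics):
                    theta_sum[d, t] += (ndk[d, t] + alpha) / denom
            for t in range(n_topics):
                denom = nk[t] + vbeta
                for w in range(n_words):
                    phi_sum[t, w] += (nkw[t, w] + beta) / denom
    return theta_sum / n_samples, phi_sum / n_samples, n_samples


@nb.njit(cache=False)
def gibbs_foldin(
    word_ids,
    phi,
    alpha,
    n_iterations,
    burn_in,
    sample_lag,
    seed,
):
    """Infer a topic mixture for one document against a fixed phi.

    Samples z for the document's tokens with p(z=k) ∝ (n_dk + α) φ_kw and
    returns the averaged (n_dk + α)/(n_d + Kα) estimate.
    """
    n_topics = phi.shape[0]
    n_tokens = word_ids.shape[0]
    state = np.empty(1, np.uint64)
    state[0] = _splitmix64(np.uint64(seed))
    theta_sum = np.zeros(n_topics, np.float64)
    if n_tokens == 0:
        theta_sum[:] = 1.0 / n_topics
        return theta_sum
    z = np.empty(n_tokens, np.int64)
    ndk = np.zeros(n_topics, np.int64)
    for i in range(n_tokens):
        k = int(_uniform(state) * n_topics)
        if k >= n_topics:
            k = n_topics - 1
        z[i] = k
        ndk[k] += 1
    cum = np.empty(n_topics, np.float64)
    n_samples = 0
    for it in range(n_iterations):
        for i in range(n_tokens):
            w = word_ids[i]
            k = z[i]
            ndk[k] -= 1
            total = 0.0
            for t in range(n_topics):
                total += (ndk[t] + alpha) * phi[t, w]
                cum[t] = total
            u = _uniform(state) * total
            k = 0
            while k < n_topics - 1 and cum[k] <= u:
                k += 1
            z[i] = k
            ndk[k] += 1
        if it >= burn_in and (it - burn_in) % sample_lag == 0:
            n_samples += 1
            denom = n_tokens + n_topics * alpha
            for t in range(n_topics):
                theta_sum[t] += (ndk[t] + alpha) / denom
    return theta_sum / n_samples
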