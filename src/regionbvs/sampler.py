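"""Sparse Bayesian variable-selection regression over one SNP region.

The model: a response (continuous trait, or latent Gaussian liability for
a binary trait under a probit link) is regressed on an unknown sparse
subset gamma of the region's SNP dosage columns,

    w = mu 1 + X_gamma beta + eps,     eps ~ N(0, I),
    beta_j | h, gamma ~ N(0, sigma_a^2),   mu ~ N(0, tau0^2),

with the slab variance tied to h, the proportion of phenotypic variance
explained by the included SNPs:

    sigma_a^2 = h / ((1 - h) * sum_{j in gamma} s_j^2),

where s_j^2 is the sample variance of SNP j's dosages.  Priors: h uniform
on [h_min, h_max]; the per-SNP inclusion probability pi uniform on the
log10 scale between bounds implying an expected 1-5 relevant SNPs in a
region (scaled by region size); model size |gamma| hard-capped.

Posterior exploration is Metropolis-within-Gibbs: add/remove/switch
proposals on gamma accepted by the analytically integrated marginal
likelihood (mu, beta integrated out), reflected random-walk updates of h
and log10 pi, and — for binary traits — latent-liability data augmentation
with conjugate Gibbs draws of (mu, beta) and truncated-normal draws of
each subject's liability.  Per-SNP posterior inclusion probabilities
(PIPs) are post-burn-in inclusion frequencies.

The numerical core is compiled with numba; a NumPy/SciPy reference
implementation of the marginal likelihood is exported for testing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit
from scipy.linalg import solve_triangular

from .genotypes import GenotypeError, GenotypeMatrix, PhenotypeVector

LOG2PI = math.log(2.0 * math.pi)


class SamplerError(ValueError):
    pass


# ---------------------------------------------------------------------------
# priors / configuration
# ---------------------------------------------------------------------------

@dataclass
class BVSPriors:
    """Prior specification for the region sampler.

    h_min/h_max bound the uniform prior on the variance explained by the
    included SNPs (defaults 0.01%-1%, the plausible per-region signal for
    a highly polygenic trait).  target_size_min/max give the expected
    number of relevant SNPs for a 1000-SNP region; the sparsity prior is
    log10(pi) uniform on [log10(min/p), log10(max/p)] for a region of p
    SNPs.  max_model_size caps |gamma| outright.
    """

    h_min: float = 1e-4
    h_max: float = 0.01
    target_size_min: float = 1.0
    target_size_max: float = 5.0
    max_model_size: int = 5
    intercept_var: float = 100.0
    h_grid: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.h_min < self.h_max < 1.0:
            raise SamplerError("require 0 < h_min < h_max < 1")
        if not 1.0 <= self.target_size_min <= self.target_size_max:
            raise SamplerError("require 1 <= target_size_min <= target_size_max")
        if self.max_model_size < 1:
            raise SamplerError("max_model_size must be >= 1")
        if self.h_grid is not None:
            grid = np.asarray(self.h_grid, dtype=float)
            if grid.size == 0 or np.any((grid <= 0) | (grid >= 1)):
                raise SamplerError("h_grid values must lie in (0, 1)")
            self.h_grid = grid

    def log10_pi_bounds(self, region_size: int) -> tuple[float, float]:
        """Sparsity-prior box for a region of ``region_size`` SNPs."""
        lo = math.log10(self.target_size_min / region_size)
        hi = math.log10(min(self.target_size_max / region_size, 0.9))
        if hi < lo:
            lo = hi
        return lo, hi


@dataclass
class BVSConfig:
    """MCMC run configuration.

    The full-protocol default is one million iterations per region; the
    package default of 1e5 keeps routine runs fast.  burn_in is a fraction
    of n_iter; traces are recorded every ``thin`` iterations.
    """

    n_iter: int = 100_000
    burn_in: float = 0.2
    thin: int = 10
    n_chains: int = 1
    seed: int = 0
    trait_mode: str = "binary"
    step_h: float | None = None
    step_log10_pi: float = 0.25

    def __post_init__(self) -> None:
        if self.n_iter < 1000:
            raise SamplerError("n_iter must be >= 1000")
        if not 0.0 <= self.burn_in < 1.0:
            raise SamplerError("burn_in must be a fraction < 1")
        if self.thin < 1 or self.n_chains < 1:
            raise SamplerError("thin and n_chains must be >= 1")
        if self.trait_mode not in {"binary", "continuous"}:
            raise SamplerError("trait_mode must be 'binary' or 'continuous'")

    @property
    def n_burn(self) -> int:
        return int(self.burn_in * self.n_iter)


@dataclass
class BVSModelState:
    """One Markov-chain state (exposed for stepwise use and testing)."""

    gamma: list[int]
    h: float
    log10_pi: float
    z: np.ndarray | None = None     # latent liabilities (binary mode)
    mu: float = 0.0
    beta: np.ndarray | None = None
    log_ml: float = float("nan")


@dataclass
class BVSResult:
    """Per-SNP PIPs with traces and convergence diagnostics."""

    pip: np.ndarray
    traces: dict[str, np.ndarray]       # each (n_chains, n_kept)
    n_kept_burn: int                    # kept samples falling in burn-in
    gelman_rubin: dict[str, float] | None
    acceptance: dict[str, float]
    n_iter: int
    snp_ids: np.ndarray | None = None

    @property
    def sum_pip(self) -> float:
        return float(self.pip.sum())

    @property
    def mean_pip(self) -> float:
        return float(self.pip.mean())


# ---------------------------------------------------------------------------
# reference marginal likelihood (NumPy/SciPy)
# ---------------------------------------------------------------------------

def log_marginal_likelihood(
    response: np.ndarray,
    X_gamma: np.ndarray | None,
    h: float,
    snp_variances: np.ndarray | None,
    intercept_var: float = 100.0,
) -> float:
    """log p(response | gamma, h) with (mu, beta) integrated out.

    ``response`` is the latent liability z in probit mode or the trait y in
    continuous mode; residual variance is fixed at 1.  With an empty gamma
    this reduces to the intercept-only marginal.
    """
    w = np.asarray(response, dtype=float).ravel()
    n = w.size
    if X_gamma is None or (hasattr(X_gamma, "size") and np.asarray(X_gamma).size == 0):
        k = 0
        W = np.ones((n, 1))
        v = np.array([intercept_var])
    else:
        X = np.atleast_2d(np.asarray(X_gamma, dtype=float))
        if X.shape[0] != n:
            X = X.T
        k = X.shape[1]
        if not 0.0 < h < 1.0:
            raise SamplerError(f"h must lie in (0, 1), got {h}")
        s2 = np.asarray(snp_variances, dtype=float).ravel()
        if s2.size != k:
            raise SamplerError("one snp variance required per included SNP")
        if np.any(s2 <= 0):
            raise SamplerError("included SNP with zero dosage variance")
        sigma_a2 = h / ((1.0 - h) * s2.sum())
        W = np.column_stack([np.ones(n), X])
        v = np.concatenate([[intercept_var], np.full(k, sigma_a2)])
    M = np.diag(1.0 / v) + W.T @ W
    L = np.linalg.cholesky(M)
    u = solve_triangular(L, W.T @ w, lower=True)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    return float(
        -0.5 * (n * LOG2PI + np.log(v).sum() + logdet + w @ w - u @ u)
    )


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def _build_mb(X, s2, w, glist, k, h, tau0, M, b):
    """Fill M = V^{-1} + W'W and b = W'w for W = [1, X_gamma]; return sum log v.

    Only the leading (k+1) x (k+1) block of the workspace M (and k+1
    entries of b) is written and read.
    """
    n = X.shape[0]
    sw = 0.0
    for i in range(n):
        sw += w[i]
    b[0] = sw
    M[0, 0] = n + 1.0 / tau0
    sum_logv = np.log(tau0)
    if k > 0:
        s2sum = 0.0
        for a in range(k):
            s2sum += s2[glist[a]]
        siga2 = h / ((1.0 - h) * s2sum)
        for a in range(k):
            j = glist[a]
            cs = 0.0
            dw = 0.0
            for i in range(n):
                xij = X[i, j]
                cs += xij
                dw += xij * w[i]
            M[0, a + 1] = cs
            M[a + 1, 0] = cs
            b[a + 1] = dw
        for a in range(k):
            ja = glist[a]
            for c in range(a, k):
                jc = glist[c]
                d = 0.0
                for i in range(n):
                    d += X[i, ja] * X[i, jc]
                M[a + 1, c + 1] = d
                M[c + 1, a + 1] = d
        for a in range(k):
            M[a + 1, a + 1] += 1.0 / siga2
            sum_logv += np.log(siga2)
    return sum_logv


@njit(cache=True)
def _chol_inplace(M, m):
    """Lower Cholesky of the leading m x m block of M, in place; returns log det."""
    logdet = 0.0
    for c in range(m):
        s = M[c, c]
        for t in range(c):
            s -= M[c, t] * M[c, t]
        d = np.sqrt(s)
        M[c, c] = d
        logdet += 2.0 * np.log(d)
        for r in range(c + 1, m):
            s = M[r, c]
            for t in range(c):
                s -= M[r, t] * M[c, t]
            M[r, c] = s / d
    return logdet


@njit(cache=True)
def _logml_ws(X, s2, w, ww, glist, k, h, tau0, M, b):
    """Marginal log-likelihood using caller-provided workspace M/b."""
    n = X.shape[0]
    m = k + 1
    sum_logv = _build_mb(X, s2, w, glist, k, h, tau0, M, b)
    logdet = _chol_inplace(M, m)
    for i in range(m):
        s = b[i]
        for t in range(i):
            s -= M[i, t] * b[t]
        b[i] = s / M[i, i]
    q = ww
    for i in range(m):
        q -= b[i] * b[i]
    return -0.5 * (n * LOG2PI + sum_logv + logdet + q)


@njit(cache=True)
def _logml_core(X, s2, w, ww, glist, k, h, tau0):
    M = np.empty((k + 1, k + 1))
    b = np.empty(k + 1)
    return _logml_ws(X, s2, w, ww, glist, k, h, tau0, M, b)


@njit(cache=True)
def _tnorm_pos(mu):
    """Draw from N(mu, 1) truncated to (0, inf)."""
    a = -mu
    if a <= 0.3:
        while True:
            x = np.random.normal()
            if x > a:
                return mu + x
    # Robert's exponential rejection for deep truncation
    alpha = 0.5 * (a + np.sqrt(a * a + 4.0))
    while True:
        x = a - np.log(1.0 - np.random.random()) / alpha
        d = x - alpha
        if np.random.random() <= np.exp(-0.5 * d * d):
            return mu + x


@njit(cache=True)
def _reflect(x, lo, hi):
    span = hi - lo
    ypos = (x - lo) % (2.0 * span)
    if ypos < 0.0:
        ypos += 2.0 * span
    if ypos > span:
        ypos = 2.0 * span - ypos
    return lo + ypos


@njit(cache=True)
def _nth_excluded(inc, u):
    cnt = -1
    for j in range(inc.shape[0]):
        if not inc[j]:
            cnt += 1
            if cnt == u:
                return j
    return inc.shape[0] - 1  # unreachable in contract


@njit(cache=True)
def _gibbs_z(X, s2, w, yb, glist, k, h, tau0, coef_out, M, b):
    """Draw (mu, beta) | w then each w_i | coef from its truncated normal."""
    n = X.shape[0]
    m = k + 1
    _build_mb(X, s2, w, glist, k, h, tau0, M, b)
    _chol_inplace(M, m)
    for i in range(m):
        s = b[i]
        for t in range(i):
            s -= M[i, t] * b[t]
        b[i] = s / M[i, i]
    for i in range(m):
        b[i] += np.random.normal()
    for i in range(m - 1, -1, -1):
        s = b[i]
        for t in range(i + 1, m):
            s -= M[t, i] * b[t]
        b[i] = s / M[i, i]
    for i in range(m):
        coef_out[i] = b[i]
    for i in range(n):
        eta = b[0]
        for a in range(k):
            eta += b[a + 1] * X[i, glist[a]]
        if yb[i] == 1:
            w[i] = _tnorm_pos(eta)
        else:
            w[i] = -_tnorm_pos(-eta)


@njit(cache=True)
def _sweep(X, s2, w, yb, is_binary, inc, glist, ints, flts,
           h_min, h_max, lpi_min, lpi_max, max_k, tau0,
           h_grid, step_h, step_lpi, acc, coef_out, Mbuf, bbuf):
    """One MCMC sweep; mutates inc/glist/w/ints/flts/acc/coef_out.

    ints = [k]; flts = [h, log10_pi, cur_logml, ww].
    acc counts proposed/accepted per move:
    [add_p, add_a, rem_p, rem_a, sw_p, sw_a, h_p, h_a, pi_p, pi_a].
    """
    n, p = X.shape
    k = ints[0]
    h = flts[0]
    lpi = flts[1]
    cur = flts[2]
    ww = flts[3]
    pi = 10.0 ** lpi

    # ---- gamma move: add / remove / switch
    mv = np.random.randint(3)
    if mv == 0:
        acc[0] += 1
        if k < max_k and k < p:
            j = _nth_excluded(inc, np.random.randint(p - k))
            glist[k] = j
            ml = _logml_ws(X, s2, w, ww, glist, k + 1, h, tau0, Mbuf, bbuf)
            logr = (ml - cur + np.log(pi) - np.log(1.0 - pi)
                    + np.log(p - k) - np.log(k + 1.0))
            if np.log(np.random.random()) < logr:
                inc[j] = True
                k += 1
                cur = ml
                acc[1] += 1
    elif mv == 1:
        acc[2] += 1
        if k > 0:
            a = np.random.randint(k)
            j = glist[a]
            glist[a] = glist[k - 1]
            glist[k - 1] = j
            ml = _logml_ws(X, s2, w, ww, glist, k - 1, h, tau0, Mbuf, bbuf)
            logr = (ml - cur + np.log(1.0 - pi) - np.log(pi)
                    + np.log(1.0 * k) - np.log(p - k + 1.0))
            if np.log(np.random.random()) < logr:
                inc[j] = False
                k -= 1
                cur = ml
                acc[3] += 1
    else:
        acc[4] += 1
        if 0 < k < p:
            a = np.random.randint(k)
            jold = glist[a]
            jnew = _nth_excluded(inc, np.random.randint(p - k))
            glist[a] = jnew
            ml = _logml_ws(X, s2, w, ww, glist, k, h, tau0, Mbuf, bbuf)
            if np.log(np.random.random()) < ml - cur:
                inc[jold] = False
                inc[jnew] = True
                cur = ml
                acc[5] += 1
            else:
                glist[a] = jold

    # ---- h update (random walk in the prior box, or grid redraw)
    ng = h_grid.shape[0]
    if ng > 1 or (ng == 0 and h_max > h_min):
        acc[6] += 1
        if ng > 0:
            hn = h_grid[np.random.randint(ng)]
        else:
            hn = _reflect(h + step_h * np.random.normal(), h_min, h_max)
        if k == 0:
            h = hn
            acc[7] += 1
        else:
            ml = _logml_ws(X, s2, w, ww, glist, k, hn, tau0, Mbuf, bbuf)
            if np.log(np.random.random()) < ml - cur:
                h = hn
                cur = ml
                acc[7] += 1

    # ---- log10 pi update (marginal likelihood free; prior-on-gamma ratio)
    if lpi_max > lpi_min:
        acc[8] += 1
        lpn = _reflect(lpi + step_lpi * np.random.normal(), lpi_min, lpi_max)
        pin = 10.0 ** lpn
        logr = k * (np.log(pin) - np.log(pi)) + (p - k) * (
            np.log(1.0 - pin) - np.log(1.0 - pi))
        if np.log(np.random.random()) < logr:
            lpi = lpn
            acc[9] += 1

    # ---- probit latent-liability augmentation
    if is_binary:
        _gibbs_z(X, s2, w, yb, glist, k, h, tau0, coef_out, Mbuf, bbuf)
        ww = 0.0
        for i in range(n):
            ww += w[i] * w[i]
        cur = _logml_ws(X, s2, w, ww, glist, k, h, tau0, Mbuf, bbuf)

    ints[0] = k
    flts[0] = h
    flts[1] = lpi
    flts[2] = cur
    flts[3] = ww


@njit(cache=True)
def _run_chain(X, s2, resp, yb, is_binary,
               h_min, h_max, lpi_min, lpi_max, max_k, tau0,
               h_grid, step_h, step_lpi,
               n_iter, n_burn, thin, seed):
    np.random.seed(seed)
    n, p = X.shape
    ng = h_grid.shape[0]
    if ng > 0:
        h = h_grid[np.random.randint(ng)]
    else:
        h = h_min + (h_max - h_min) * np.random.random()
    lpi = lpi_min + (lpi_max - lpi_min) * np.random.random()
    inc = np.zeros(p, np.bool_)
    glist = np.zeros(max_k, np.int64)
    if is_binary:
        w = np.empty(n)
        for i in range(n):
            w[i] = 0.7 if yb[i] == 1 else -0.7
    else:
        w = resp.copy()
    ww = 0.0
    for i in range(n):
        ww += w[i] * w[i]
    cur = _logml_core(X, s2, w, ww, glist, 0, h, tau0)
    ints = np.zeros(1, np.int64)
    flts = np.array([h, lpi, cur, ww])
    acc = np.zeros(10, np.int64)
    coef_out = np.zeros(max_k + 1)
    Mbuf = np.empty((max_k + 1, max_k + 1))
    bbuf = np.empty(max_k + 1)
    n_keep = (n_iter + thin - 1) // thin
    tr_h = np.empty(n_keep)
    tr_lpi = np.empty(n_keep)
    tr_k = np.empty(n_keep)
    tr_lj = np.empty(n_keep)
    pip_counts = np.zeros(p, np.int64)
    kept = 0
    for it in range(n_iter):
        _sweep(X, s2, w, yb, is_binary, inc, glist, ints, flts,
               h_min, h_max, lpi_min, lpi_max, max_k, tau0,
               h_grid, step_h, step_lpi, acc, coef_out, Mbuf, bbuf)
        k = ints[0]
        if it >= n_burn:
            for a in range(k):
                pip_counts[glist[a]] += 1
        if it % thin == 0:
            pi2 = 10.0 ** flts[1]
            tr_h[kept] = flts[0]
            tr_lpi[kept] = flts[1]
            tr_k[kept] = k
            tr_lj[kept] = flts[2] + k * np.log(pi2) + (p - k) * np.log(1.0 - pi2)
            kept += 1
    return pip_counts, tr_h, tr_lpi, tr_k, tr_lj, acc


# ---------------------------------------------------------------------------
# Python driver
# ---------------------------------------------------------------------------

def _prepare_region(G_region, y, config: BVSConfig):
    """Extract dosage matrix, SNP variances and response arrays."""
    snp_ids = None
    if isinstance(G_region, GenotypeMatrix):
        if G_region.has_missing:
            raise SamplerError(
                "region contains missing dosages; run impute_missing_mean first"
            )
        X = G_region.dosages
        snp_ids = G_region.snp_meta["snp_id"].to_numpy()
    else:
        X = np.asarray(G_region, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise SamplerError("region must be a non-empty subjects x SNPs matrix")

    if config.trait_mode == "binary":
        if isinstance(y, PhenotypeVector):
            yb = y.labels.astype(np.int8)
        else:
            yb = np.asarray(y).astype(np.int8)
            if set(np.unique(yb).tolist()) != {0, 1}:
                raise SamplerError(
                    "binary trait requires both case and control labels"
                )
        if len(yb) != X.shape[0]:
            raise SamplerError("phenotype length does not match subject count")
        resp = np.zeros(X.shape[0])
    else:
        resp = np.asarray(y, dtype=float).ravel()
        if resp.size != X.shape[0]:
            raise SamplerError("response length does not match subject count")
        yb = np.zeros(X.shape[0], dtype=np.int8)
    return np.asfortranarray(X, dtype=np.float64), yb, resp, snp_ids


def run_bvs(
    G_region,
    y,
    priors: BVSPriors | None = None,
    config: BVSConfig | None = None,
) -> BVSResult:
    """Run the region sampler; returns PIPs, traces and diagnostics.

    Monomorphic (zero-variance) SNP columns cannot carry signal and are
    excluded from the search; their PIP is reported as 0.  The sparsity
    prior is scaled by the full region size.
    """
    priors = priors or BVSPriors()
    config = config or BVSConfig()
    X, yb, resp, snp_ids = _prepare_region(G_region, y, config)
    n, p_full = X.shape
    s2_all = np.var(X, axis=0, ddof=1)
    active = np.where(s2_all > 0)[0]
    if active.size == 0:
        raise SamplerError("all SNPs in the region are monomorphic")
    Xa = np.asfortranarray(X[:, active])
    s2 = s2_all[active]
    lpi_lo, lpi_hi = priors.log10_pi_bounds(p_full)
    max_k = int(min(priors.max_model_size, active.size))
    is_binary = config.trait_mode == "binary"
    grid = (
        np.asarray(priors.h_grid, dtype=float)
        if priors.h_grid is not None
        else np.empty(0)
    )
    step_h = (
        config.step_h
        if config.step_h is not None
        else (priors.h_max - priors.h_min) / 8.0
    )

    chain_seeds = (
        np.random.SeedSequence(config.seed).generate_state(config.n_chains)
        >> 1
    ).astype(np.int64)
    n_burn = config.n_burn
    pip_counts = np.zeros(active.size, dtype=np.int64)
    tr_h = []
    tr_lpi = []
    tr_k = []
    tr_lj = []
    acc_total = np.zeros(10, dtype=np.int64)
    for c in range(config.n_chains):
        counts, h_c, lpi_c, k_c, lj_c, acc = _run_chain(
            Xa, s2, resp, yb, is_binary,
            priors.h_min, priors.h_max, lpi_lo, lpi_hi, max_k,
            priors.intercept_var, grid, step_h, config.step_log10_pi,
            config.n_iter, n_burn, config.thin, int(chain_seeds[c]),
        )
        pip_counts += counts
        tr_h.append(h_c)
        tr_lpi.append(lpi_c)
        tr_k.append(k_c)
        tr_lj.append(lj_c)
        acc_total += acc

    denom = (config.n_iter - n_burn) * config.n_chains
    pip = np.zeros(p_full)
    pip[active] = pip_counts / denom
    traces = {
        "h": np.vstack(tr_h),
        "log10_pi": np.vstack(tr_lpi),
        "model_size": np.vstack(tr_k),
        "log_joint": np.vstack(tr_lj),
    }
    n_kept_burn = int(math.ceil(n_burn / config.thin))
    gr = None
    if config.n_chains >= 2:
        gr = {
            "h": gelman_rubin(traces["h"][:, n_kept_burn:]),
            "log_joint": gelman_rubin(traces["log_joint"][:, n_kept_burn:]),
        }
    names = ["add", "remove", "switch", "h", "log10_pi"]
    acceptance = {}
    for i, nm in enumerate(names):
        prop = acc_total[2 * i]
        acceptance[nm] = float(acc_total[2 * i + 1] / prop) if prop else float("nan")
    return BVSResult(
        pip=pip,
        traces=traces,
        n_kept_burn=n_kept_burn,
        gelman_rubin=gr,
        acceptance=acceptance,
        n_iter=config.n_iter,
        snp_ids=snp_ids,
    )


class RegionRunner:
    """Reusable single-chain runner for one region.

    Prepares the dosage matrix, SNP variances and prior bounds once so the
    permutation engine can re-run the sampler thousands of times (fresh
    chain per call) with minimal per-call overhead.  Statistics are the
    sum and mean of PIPs over the full region.
    """

    def __init__(self, G_region, priors: BVSPriors, config: BVSConfig):
        self.priors = priors
        self.config = config
        X, _, _, self.snp_ids = _prepare_region(
            G_region, np.zeros(np.asarray(
                G_region.dosages if isinstance(G_region, GenotypeMatrix) else G_region
            ).shape[0]), BVSConfig(
                n_iter=config.n_iter, burn_in=config.burn_in, thin=config.thin,
                seed=config.seed, trait_mode="continuous",
            ),
        )
        self.n, self.p_full = X.shape
        s2_all = np.var(X, axis=0, ddof=1)
        active = np.where(s2_all > 0)[0]
        if active.size == 0:
            raise SamplerError("all SNPs in the region are monomorphic")
        self.X = np.asfortranarray(X[:, active])
        self.s2 = s2_all[active]
        self.active = active
        self.lpi_lo, self.lpi_hi = priors.log10_pi_bounds(self.p_full)
        self.max_k = int(min(priors.max_model_size, active.size))
        self.grid = (
            np.asarray(priors.h_grid, dtype=float)
            if priors.h_grid is not None
            else np.empty(0)
        )
        self.step_h = (
            config.step_h
            if config.step_h is not None
            else (priors.h_max - priors.h_min) / 8.0
        )
        self.is_binary = config.trait_mode == "binary"
        self.denom = config.n_iter - config.n_burn

    def pip(self, y, seed: int) -> np.ndarray:
        """PIPs from one fresh chain on response/labels ``y``."""
        if self.is_binary:
            yb = (y.labels if isinstance(y, PhenotypeVector) else np.asarray(y)).astype(np.int8)
            resp = np.zeros(self.n)
        else:
            resp = np.asarray(y, dtype=float).ravel()
            yb = np.zeros(self.n, dtype=np.int8)
        counts = _run_chain(
            self.X, self.s2, resp, yb, self.is_binary,
            self.priors.h_min, self.priors.h_max, self.lpi_lo, self.lpi_hi,
            self.max_k, self.priors.intercept_var, self.grid, self.step_h,
            self.config.step_log10_pi, self.config.n_iter, self.config.n_burn,
            self.config.thin, int(seed),
        )[0]
        pip = np.zeros(self.p_full)
        pip[self.active] = counts / self.denom
        return pip

    def stat(self, y, seed: int, statistic: str = "sum_pip") -> float:
        pip = self.pip(y, seed)
        total = float(pip.sum())
        return total if statistic == "sum_pip" else total / self.p_full


def mcmc_step(
    state: BVSModelState,
    data: tuple,
    priors: BVSPriors,
    seed: int,
    trait_mode: str = "binary",
    step_h: float | None = None,
    step_log10_pi: float = 0.25,
) -> BVSModelState:
    """Advance one sweep from ``state``; ``data`` is (X, y).

    Exposed for stepwise inspection and testing; `run_bvs` drives the same
    compiled sweep in a tight loop.
    """
    X_in, y = data
    cfg = BVSConfig(n_iter=1000, trait_mode=trait_mode)
    X, yb, resp, _ = _prepare_region(X_in, y, cfg)
    n, p = X.shape
    s2 = np.var(X, axis=0, ddof=1)
    if np.any(s2 <= 0):
        raise SamplerError("mcmc_step requires polymorphic SNP columns")
    lpi_lo, lpi_hi = priors.log10_pi_bounds(p)
    max_k = int(min(priors.max_model_size, p))
    is_binary = trait_mode == "binary"
    grid = (
        np.asarray(priors.h_grid, dtype=float)
        if priors.h_grid is not None
        else np.empty(0)
    )
    if step_h is None:
        step_h = (priors.h_max - priors.h_min) / 8.0

    inc = np.zeros(p, dtype=np.bool_)
    glist = np.zeros(max_k, dtype=np.int64)
    for a, j in enumerate(state.gamma):
        if a >= max_k:
            raise SamplerError("state.gamma exceeds max_model_size")
        inc[j] = True
        glist[a] = j
    k = len(state.gamma)
    if is_binary:
        if state.z is None:
            w = np.where(yb == 1, 0.7, -0.7).astype(float)
        else:
            w = np.asarray(state.z, dtype=float).copy()
    else:
        w = resp.copy()
    ww = float(w @ w)
    cur = _logml_core(X, s2, w, ww, glist, k, state.h, priors.intercept_var)
    ints = np.array([k], dtype=np.int64)
    flts = np.array([state.h, state.log10_pi, cur, ww])
    acc = np.zeros(10, dtype=np.int64)
    coef_out = np.zeros(max_k + 1)
    _seed_rng(int(seed))
    Mbuf = np.empty((max_k + 1, max_k + 1))
    bbuf = np.empty(max_k + 1)
    _sweep(X, s2, w, yb, is_binary, inc, glist, ints, flts,
           priors.h_min, priors.h_max, lpi_lo, lpi_hi, max_k,
           priors.intercept_var, grid, step_h, step_log10_pi, acc, coef_out,
           Mbuf, bbuf)
    k_new = int(ints[0])
    return BVSModelState(
        gamma=sorted(int(j) for j in glist[:k_new]),
        h=float(flts[0]),
        log10_pi=float(flts[1]),
        z=w if is_binary else None,
        mu=float(coef_out[0]),
        beta=coef_out[1 : k_new + 1].copy() if is_binary else None,
        log_ml=float(flts[2]),
    )


def gelman_rubin(traces) -> float:
    """Potential scale reduction factor sqrt((n-1)/n + B/(n W)).

    ``traces`` is a (chains, samples) array or a list of equal-length
    scalar sequences.  A zero within-chain variance triggers a warning;
    the value is inf when chains disagree with no within-chain spread,
    and the degenerate B = W = 0 case returns sqrt((n-1)/n).
    """
    arr = np.asarray(traces, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise SamplerError("gelman_rubin needs >= 2 chains of equal length")
    m, n = arr.shape
    if n < 10:
        raise SamplerError("gelman_rubin needs chains of length >= 10")
    chain_vars = arr.var(axis=1, ddof=1)
    W = chain_vars.mean()
    B = n * arr.mean(axis=1).var(ddof=1)
    if W == 0.0:
        warnings.warn("zero within-chain variance in Gelman-Rubin diagnostic")
        if B == 0.0:
            return math.sqrt((n - 1) / n)
        return float("inf")
    return float(math.sqrt((n - 1) / n + B / (n * W)))
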