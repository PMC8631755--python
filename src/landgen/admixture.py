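"""Spatial Bayesian admixture with environmental covariates.

A fully specified stand-in for covariate-aware spatial Bayesian
clustering: individual ancestry is a logistic-normal
regression on standardized climate covariates plus a low-order spatial
trend,

    z_ik = beta_k . x_i + gamma_k . s_i + eps_ik,   eps ~ N(0, sigma^2)
    Q_i  = softmax(z_i)                (reference cluster K has z = 0)

and gene copies are allocated to clusters by data augmentation with
cluster-specific allele (or haplotype) frequencies. The sampler is
Metropolis-within-Gibbs:

* allocations  — exact multinomial draw, prob ∝ Q_ik f[k, l, a];
* frequencies  — Dirichlet conjugacy on allocation counts;
* z            — per-individual random-walk Metropolis (vectorized);
* beta, gamma  — Gaussian conjugate regression update given z;
* sigma^2      — inverse-gamma conjugacy.

Model choice uses DIC = mean deviance + p_D with
p_D = mean deviance - deviance at posterior means (Spiegelhalter).
Future climates are projected through the regression component only:
Q'_ik = softmax(beta_hat . x'_i + gamma_hat . s_i).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .genetics import MISSING, GenotypeTable, HaplotypeSet
from .raster import RasterStack

__all__ = [
    "AdmixtureFit",
    "TurnoverReport",
    "encode_genotypes",
    "encode_haplotypes",
    "select_covariates",
    "fit",
    "select_runs",
    "project",
    "ancestry_correlation",
    "align_clusters",
    "turnover",
    "render_cluster_map",
]


@dataclass
class AdmixtureFit:
    """Posterior summary of one MCMC run."""

    Q: np.ndarray                  # (n, K) posterior-mean ancestry
    beta: np.ndarray               # (K-1, p+1) covariate coefficients (posterior mean)
    gamma: np.ndarray              # (K-1, 3) spatial trend [1, lon, lat]
    sigma: float
    freqs: list[np.ndarray]        # per locus: (K, n_alleles) posterior-mean freqs
    K: int
    dic: float
    mean_deviance: float
    p_d: float
    deviance_trace: np.ndarray
    seed: int
    sweeps: int
    burn_in: int
    covariate_names: list[str] = field(default_factory=list)
    cov_mean: np.ndarray | None = None
    cov_sd: np.ndarray | None = None
    coords_mean: np.ndarray | None = None
    coords_sd: np.ndarray | None = None


@dataclass
class TurnoverReport:
    overall_r: float
    per_cluster_r: np.ndarray
    lost_clusters: list[int]
    threshold: float


# ---------------------------------------------------------------------------
# data encoding


def encode_genotypes(gt: GenotypeTable) -> list[np.ndarray]:
    """Per-locus (n_ind, 2) arrays of allele indices (-1 = missing)."""
    out = []
    for l in range(gt.n_loci):
        calls = gt.alleles[:, l, :]
        alleles = np.unique(calls[calls != MISSING])
        index = {a: i for i, a in enumerate(alleles)}
        enc = np.full(calls.shape, -1, dtype=int)
        for a, i in index.items():
            enc[calls == a] = i
        out.append(enc)
    return out


def encode_haplotypes(haps: HaplotypeSet) -> list[np.ndarray]:
    """Single pseudo-locus with one copy per individual (haploid)."""
    ids = sorted(set(haps.haplotype_ids))
    index = {h: i for i, h in enumerate(ids)}
    enc = np.array([[index[h]] for h in haps.haplotype_ids], dtype=int)
    return [enc]


def select_covariates(stack: RasterStack, pops, m: int = 3
                      ) -> tuple[np.ndarray, list[str]]:
    """Pick the ``m`` layers with the highest among-population variance
    (after standardizing each layer by its full-grid spread, so layers
    on different scales compete fairly) and return their values at the
    population coordinates plus the chosen names."""
    X = stack.values_at_points(pops.lons, pops.lats)
    _, _, grid_vals = stack.table()
    grid_sd = np.where(grid_vals.std(axis=0) > 1e-12, grid_vals.std(axis=0), 1.0)
    score = (X / grid_sd).var(axis=0)
    order = np.argsort(-score)[:m]
    names = [stack.names[i] for i in order]
    return X[:, order], names


# ---------------------------------------------------------------------------
# likelihood helpers


def _softmax_rows(Z: np.ndarray) -> np.ndarray:
    Z = Z - Z.max(axis=1, keepdims=True)
    E = np.exp(Z)
    return E / E.sum(axis=1, keepdims=True)


def _deviance(Q: np.ndarray, freqs: list[np.ndarray], loci: list[np.ndarray]
              ) -> float:
    """-2 log L of the observed gene copies given ancestry and cluster
    frequencies, marginalizing the copy's cluster."""
    ll = 0.0
    for enc, f in zip(loci, freqs):
        for c in range(enc.shape[1]):
            a = enc[:, c]
            ok = a >= 0
            if not ok.any():
                continue
            p = np.einsum("ik,ik->i", Q[ok], f[:, a[ok]].T)
            ll += np.log(np.clip(p, 1e-300, None)).sum()
    return -2.0 * ll


# ---------------------------------------------------------------------------
# the sampler


def fit(
    loci: list[np.ndarray],
    coords: np.ndarray,
    covariates: np.ndarray,
    K_max: int,
    sweeps: int = 2000,
    burn_in: int = 200,
    seed: int = 0,
    thin: int = 10,
    covariate_names: list[str] | None = None,
    step0: float = 0.3,
) -> AdmixtureFit:
    """Run the MCMC and return posterior means and the DIC.

    ``loci`` is the output of :func:`encode_genotypes` (or
    :func:`encode_haplotypes`); ``coords`` is (n, 2) lon/lat;
    ``covariates`` is (n, p) raw climate values (standardized
    internally, with the scaling stored on the fit for projection).
    Deterministic for a fixed seed.
    """
    coords = np.asarray(coords, dtype=float)
    covariates = np.asarray(covariates, dtype=float)
    if not np.all(np.isfinite(covariates)):
        raise ValueError("non-finite covariates")
    n = covariates.shape[0]
    K = int(K_max)
    if K < 1:
        raise ValueError("K_max must be >= 1")
    rng = np.random.default_rng(seed)

    cov_mean = covariates.mean(axis=0)
    cov_sd = np.where(covariates.std(axis=0) > 1e-12, covariates.std(axis=0), 1.0)
    Xc = (covariates - cov_mean) / cov_sd
    coo_mean = coords.mean(axis=0)
    coo_sd = np.where(coords.std(axis=0) > 1e-12, coords.std(axis=0), 1.0)
    S = (coords - coo_mean) / coo_sd
    X = np.column_stack([np.ones(n), Xc])          # (n, p+1) incl. intercept
    Sm = np.column_stack([S])                      # (n, 2) degree-1 trend
    p1 = X.shape[1]
    ps = Sm.shape[1]
    D = np.column_stack([X, Sm])                   # design for conjugate update
    d = D.shape[1]
    DtD = D.T @ D

    n_alleles = [int(enc.max()) + 1 if (enc >= 0).any() else 1 for enc in loci]

    if K == 1:
        Q = np.ones((n, 1))
        freqs = []
        for enc, A in zip(loci, n_alleles):
            counts = np.bincount(enc[enc >= 0].ravel(), minlength=A).astype(float)
            tot = counts.sum()
            freqs.append((counts / tot if tot else np.full(A, 1.0 / A))[None, :])
        dev = _deviance(Q, freqs, loci)
        return AdmixtureFit(
            Q, np.zeros((0, p1)), np.zeros((0, ps + 1)), 0.0, freqs, 1,
            dic=dev, mean_deviance=dev, p_d=0.0,
            deviance_trace=np.array([dev]), seed=seed, sweeps=sweeps,
            burn_in=burn_in, covariate_names=covariate_names or [],
            cov_mean=cov_mean, cov_sd=cov_sd, coords_mean=coo_mean,
            coords_sd=coo_sd,
        )

    # state
    theta = np.zeros((K - 1, d))                   # [beta | gamma]
    Z = np.zeros((n, K))                           # z_iK fixed at 0
    Z[:, : K - 1] = 0.1 * rng.standard_normal((n, K - 1))
    sigma2 = 1.0
    freqs = [np.full((K, A), 1.0 / A) for A in n_alleles]
    step = step0
    acc_hist: list[float] = []

    Q_sum = np.zeros((n, K))
    theta_sum = np.zeros_like(theta)
    freq_sum = [np.zeros_like(f) for f in freqs]
    dev_samples: list[float] = []
    sigma2_sum = 0.0
    n_keep = 0
    tau2 = 100.0                                   # prior variance on theta

    for sweep in range(sweeps):
        Q = _softmax_rows(Z)

        # -- allocations and frequency update (Dirichlet conjugacy)
        counts_k = np.zeros((n, K))
        for li, (enc, A) in enumerate(zip(loci, n_alleles)):
            alloc_counts = np.zeros((K, A))
            f = freqs[li]
            for c in range(enc.shape[1]):
                a = enc[:, c]
                ok = a >= 0
                if not ok.any():
                    continue
                w = Q[ok] * f[:, a[ok]].T          # (n_ok, K)
                w /= w.sum(axis=1, keepdims=True)
                u = _vector_categorical(rng, w)
                np.add.at(alloc_counts, (u, a[ok]), 1.0)
                idx = np.nonzero(ok)[0]
                np.add.at(counts_k, (idx, u), 1.0)
            g = rng.standard_gamma(alloc_counts + 1.0)
            freqs[li] = g / g.sum(axis=1, keepdims=True)

        # -- z update: per-individual random-walk Metropolis
        mu = D @ theta.T                           # (n, K-1)
        prop = Z.copy()
        prop[:, : K - 1] += step * rng.standard_normal((n, K - 1))
        logp_cur = _z_logpost(Z, mu, sigma2, counts_k)
        logp_prop = _z_logpost(prop, mu, sigma2, counts_k)
        accept = np.log(rng.random(n)) < (logp_prop - logp_cur)
        Z[accept] = prop[accept]
        rate = accept.mean()
        acc_hist.append(rate)
        if sweep < burn_in and (sweep + 1) % 25 == 0:
            step *= np.exp(0.5 * (np.mean(acc_hist[-25:]) - 0.25))
            step = float(np.clip(step, 1e-3, 5.0))

        # -- theta (beta, gamma) conjugate Gaussian update given z
        prec = DtD / sigma2 + np.eye(d) / tau2
        cov_t = np.linalg.inv(prec)
        chol = np.linalg.cholesky(cov_t)
        for k in range(K - 1):
            mean_k = cov_t @ (D.T @ Z[:, k]) / sigma2
            theta[k] = mean_k + chol @ rng.standard_normal(d)

        # -- sigma^2 inverse-gamma conjugacy (a0 = b0 = 1)
        resid = Z[:, : K - 1] - D @ theta.T
        a_post = 1.0 + 0.5 * n * (K - 1)
        b_post = 1.0 + 0.5 * (resid**2).sum()
        sigma2 = b_post / rng.standard_gamma(a_post)

        if sweep >= burn_in:
            Q = _softmax_rows(Z)
            Q_sum += Q
            theta_sum += theta
            for li in range(len(loci)):
                freq_sum[li] += freqs[li]
            sigma2_sum += sigma2
            n_keep += 1
            if (sweep - burn_in) % thin == 0:
                dev_samples.append(_deviance(Q, freqs, loci))

    if n_keep == 0:
        raise ValueError("no post-burn-in samples: increase sweeps")
    Q_mean = Q_sum / n_keep
    Q_mean /= Q_mean.sum(axis=1, keepdims=True)
    theta_mean = theta_sum / n_keep
    freqs_mean = [f / n_keep for f in freq_sum]
    dev_trace = np.array(dev_samples)
    if not np.all(np.isfinite(dev_trace)):
        raise ValueError("chain divergence: non-finite deviance in trace")
    mean_dev = float(dev_trace.mean())
    dev_at_means = _deviance(Q_mean, freqs_mean, loci)
    p_d = max(mean_dev - dev_at_means, 0.0)
    dic = mean_dev + p_d
    return AdmixtureFit(
        Q_mean, theta_mean[:, :p1], theta_mean[:, p1:],
        float(np.sqrt(sigma2_sum / n_keep)), freqs_mean, K,
        dic=float(dic), mean_deviance=mean_dev, p_d=float(p_d),
        deviance_trace=dev_trace, seed=seed, sweeps=sweeps, burn_in=burn_in,
        covariate_names=covariate_names or [], cov_mean=cov_mean,
        cov_sd=cov_sd, coords_mean=coo_mean, coords_sd=coo_sd,
    )


def _vector_categorical(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    cdf = np.cumsum(probs, axis=1)
    cdf[:, -1] = 1.0
    r = rng.random((probs.shape[0], 1))
    return (r > cdf).sum(axis=1)


def _z_logpost(Z: np.ndarray, mu: np.ndarray, sigma2: float,
               counts_k: np.ndarray) -> np.ndarray:
    """Per-individual log posterior of z (multinomial allocation
    likelihood + Gaussian regression prior), up to a constant."""
    logQ = Z - Z.max(axis=1, keepdims=True)
    logQ = logQ - np.log(np.exp(logQ).sum(axis=1, keepdims=True))
    like = (counts_k * logQ).sum(axis=1)
    prior = -0.5 * ((Z[:, : mu.shape[1]] - mu) ** 2).sum(axis=1) / sigma2
    return like + prior


# ---------------------------------------------------------------------------
# run selection, projection, turnover


def select_runs(fits: list[AdmixtureFit]) -> tuple[AdmixtureFit, pd.DataFrame]:
    """Return the fit with the lowest DIC plus the full DIC table."""
    if not fits:
        raise ValueError("no fits")
    table = pd.DataFrame(
        [{"K": f.K, "seed": f.seed, "DIC": f.dic, "p_D": f.p_d} for f in fits]
    )
    best = min(fits, key=lambda f: f.dic)
    return best, table


def regression_ancestry(fit: AdmixtureFit, covariates: np.ndarray,
                        coords: np.ndarray) -> np.ndarray:
    """Ancestry implied by the regression component alone (no
    individual-level noise): softmax(beta.x + gamma.s)."""
    covariates = np.asarray(covariates, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if fit.K == 1:
        return np.ones((covariates.shape[0], 1))
    if covariates.shape[1] != len(fit.cov_mean):
        raise ValueError("covariate count differs from the fitted model")
    Xc = (covariates - fit.cov_mean) / fit.cov_sd
    S = (coords - fit.coords_mean) / fit.coords_sd
    n = Xc.shape[0]
    X = np.column_stack([np.ones(n), Xc])
    Z = np.zeros((n, fit.K))
    Z[:, : fit.K - 1] = X @ fit.beta.T + S @ fit.gamma.T
    return _softmax_rows(Z)


def project(fit: AdmixtureFit, future_covariates: np.ndarray,
            coords: np.ndarray) -> np.ndarray:
    """Projected ancestry under a future climate: the regression
    component evaluated at the future covariates (same standardization
    as the fit; genotype data unchanged)."""
    return regression_ancestry(fit, future_covariates, coords)


def align_clusters(Q: np.ndarray, Q_ref: np.ndarray) -> np.ndarray:
    """Permute Q's columns to best match a reference (Hungarian
    assignment on column correlations); resolves label switching."""
    if Q.shape != Q_ref.shape:
        raise ValueError("shape mismatch")
    K = Q.shape[1]
    C = np.zeros((K, K))
    for i in range(K):
        for j in range(K):
            a, b = Q[:, i], Q_ref[:, j]
            if a.std() < 1e-12 or b.std() < 1e-12:
                C[i, j] = -np.mean((a - b) ** 2)
            else:
                C[i, j] = np.corrcoef(a, b)[0, 1]
    row, col = linear_sum_assignment(-C)
    perm = np.empty(K, dtype=int)
    perm[col] = row
    return Q[:, perm]


def ancestry_correlation(Q: np.ndarray, Q_proj: np.ndarray) -> float:
    """Pearson correlation of the flattened current and projected
    ancestry matrices."""
    if Q.shape != Q_proj.shape:
        raise ValueError("shape mismatch")
    return float(np.corrcoef(Q.ravel(), Q_proj.ravel())[0, 1])


def turnover(Q: np.ndarray, Q_proj: np.ndarray, threshold: float = 0.5
             ) -> TurnoverReport:
    """Per-cluster response to climate change: column-wise correlation
    between current and projected ancestry; a cluster is flagged lost
    when its maximum projected ancestry drops below ``threshold``."""
    if Q.shape != Q_proj.shape:
        raise ValueError("shape mismatch")
    K = Q.shape[1]
    per = np.empty(K)
    lost = []
    for k in range(K):
        a, b = Q[:, k], Q_proj[:, k]
        if a.std() < 1e-12 or b.std() < 1e-12:
            per[k] = np.nan
        else:
            per[k] = np.corrcoef(a, b)[0, 1]
        if Q_proj[:, k].max() < threshold:
            lost.append(k)
    return TurnoverReport(ancestry_correlation(Q, Q_proj), per, lost, threshold)


def render_cluster_map(fit: AdmixtureFit, stack: RasterStack,
                       covariate_names: list[str] | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell ancestry from the regression component over a raster
    stack; returns (argmax category grid, (K, rows, cols) ancestry)."""
    names = covariate_names or fit.covariate_names
    for nm in names:
        if nm not in stack.layers:
            raise ValueError(f"missing covariate layer {nm!r}")
    sub = stack.subset(names)
    rows, cols, X = sub.table()
    lons, lats = zip(*(stack.grid.center_of(int(r), int(c))
                       for r, c in zip(rows, cols)))
    coords = np.column_stack([lons, lats])
    Q = regression_ancestry(fit, X, coords)
    K = Q.shape[1]
    anc = np.full((K,) + stack.grid.shape, np.nan)
    cat = np.full(stack.grid.shape, -1, dtype=int)
    for k in range(K):
        anc[k, rows, cols] = Q[:, k]
    cat[rows, cols] = np.argmax(Q, axis=1)
    return cat, anc
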