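"""Bayesian admixture-model clustering of SSR genotypes.

A Gibbs sampler for the classic no-linkage admixture model: each accession
i has ancestry proportions q_i over K clusters, each cluster k has allele
frequencies p_kl per locus, and every observed allele copy originates from
cluster z ~ Categorical(q_i) with the allele drawn from p_z.  Priors are
Dirichlet(alpha) on q and Dirichlet(lambda) on p (independent frequencies
across clusters).  The marginal data likelihood per K is estimated from the
log-likelihood trace as mean(lnL) - var(lnL)/2, and the number of clusters
is chosen by the Evanno delta-K statistic

    delta_K = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K))

over independent runs.  Accessions are assigned to the cluster carrying
more than 75% of their inferred ancestry, otherwise flagged ADMIXED.

The API follows the model/results idiom: build an :class:`AdmixtureModel`
from a :class:`~ssrpop.io.GenotypeMatrix`, call :meth:`~AdmixtureModel.fit`
for one K or :meth:`~AdmixtureModel.fit_battery` for a K range, and read
estimates off the returned results objects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from .io import MISSING, GenotypeMatrix

ADMIXED = "ADMIXED"


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC settings.  Defaults are the conventional production scale
    (1e5 burn-in, 1e5 sampling iterations, 10 runs per K); use
    :meth:`desk` for test-scale settings."""

    burn_in: int = 100_000
    mcmc_iters: int = 100_000
    n_runs: int = 10
    alpha: float = 1.0
    infer_alpha: bool = False
    lam: float = 1.0

    def __post_init__(self) -> None:
        if min(self.burn_in, self.mcmc_iters, self.n_runs) <= 0:
            raise ValueError("iteration counts must be positive")
        if self.alpha <= 0 or self.lam <= 0:
            raise ValueError("alpha and lambda must be positive")

    @classmethod
    def desk(cls, **kw) -> "SamplerConfig":
        """Desk-scale settings: burn-in 2000, 5000 iterations, 5 runs."""
        defaults = dict(burn_in=2000, mcmc_iters=5000, n_runs=5)
        defaults.update(kw)
        return cls(**defaults)


@njit(cache=False)
def _gibbs_core(alleles, n_alleles, K, burn_in, n_iters, lam, alpha0,
                infer_alpha, seed):  # pragma: no cover - exercised via wrapper
    N, L, _ = alleles.shape
    amax = 0
    for j in range(L):
        if n_alleles[j] > amax:
            amax = n_alleles[j]
    np.random.seed(seed)
    alpha = alpha0
    P = np.zeros((K, L, amax))
    for k in range(K):
        for j in range(L):
            s = 0.0
            for a in range(n_alleles[j]):
                gdraw = np.random.gamma(lam, 1.0)
                P[k, j, a] = gdraw
                s += gdraw
            for a in range(n_alleles[j]):
                P[k, j, a] /= s
    Q = np.full((N, K), 1.0 / K)
    q_sum = np.zeros((N, K))
    p_sum = np.zeros((K, L, amax))
    ll_trace = np.zeros(n_iters)
    probs = np.empty(K)
    total = burn_in + n_iters
    for it in range(total):
        cp = np.zeros((K, L, amax))
        cq = np.zeros((N, K))
        ll = 0.0
        for i in range(N):
            for j in range(L):
                for c in range(2):
                    a = alleles[i, j, c]
                    if a < 0:
                        continue
                    tot = 0.0
                    for k in range(K):
                        w = Q[i, k] * P[k, j, a]
                        probs[k] = w
                        tot += w
                    ll += math.log(tot)
                    u = np.random.random() * tot
                    acc = 0.0
                    z = K - 1
                    for k in range(K):
                        acc += probs[k]
                        if u <= acc:
                            z = k
                            break
                    cp[z, j, a] += 1.0
                    cq[i, z] += 1.0
        for k in range(K):
            for j in range(L):
                s = 0.0
                for a in range(n_alleles[j]):
                    gdraw = np.random.gamma(lam + cp[k, j, a], 1.0)
                    P[k, j, a] = gdraw
                    s += gdraw
                for a in range(n_alleles[j]):
                    P[k, j, a] /= s
        sum_log_q = 0.0
        for i in range(N):
            s = 0.0
            for k in range(K):
                gdraw = np.random.gamma(alpha + cq[i, k], 1.0)
                Q[i, k] = gdraw
                s += gdraw
            for k in range(K):
                Q[i, k] /= s
                if Q[i, k] < 1e-300:
                    Q[i, k] = 1e-300
                sum_log_q += math.log(Q[i, k])
        if infer_alpha and K > 1:
            prop = alpha + np.random.normal(0.0, 0.05)
            if 0.0 < prop < 10.0:
                cur = N * (math.lgamma(K * alpha) - K * math.lgamma(alpha)) \
                    + (alpha - 1.0) * sum_log_q
                new = N * (math.lgamma(K * prop) - K * math.lgamma(prop)) \
                    + (prop - 1.0) * sum_log_q
                if math.log(np.random.random()) < new - cur:
                    alpha = prop
        if it >= burn_in:
            ll_trace[it - burn_in] = ll
            for i in range(N):
                for k in range(K):
                    q_sum[i, k] += Q[i, k]
            p_sum += P
    q_mean = q_sum / n_iters
    p_mean = p_sum / n_iters
    return q_mean, p_mean, ll_trace, alpha


def _recode(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Allele sizes -> per-locus 0-based indices; missing stays -1."""
    coded = np.full(g.calls.shape, -1, dtype=np.int64)
    n_alleles = np.zeros(g.n_loci, dtype=np.int64)
    for j in range(g.n_loci):
        sizes = np.unique(g.calls[:, j, :])
        sizes = sizes[sizes != MISSING]
        n_alleles[j] = max(len(sizes), 1)
        lookup = {int(s): idx for idx, s in enumerate(sizes)}
        for s, idx in lookup.items():
            coded[:, j, :][g.calls[:, j, :] == s] = idx
    return coded, n_alleles


@dataclass
class RunResult:
    """Posterior summaries of one MCMC run at one K."""

    K: int
    run_index: int
    ln_p_d: float
    q: pd.DataFrame                 # accession x K posterior mean ancestry
    cluster_freqs: np.ndarray       # (K, L, Amax) posterior mean frequencies
    ll_trace: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.ln_p_d):
            raise ValueError("non-finite lnP(D)")


@dataclass
class BatteryResult:
    """All runs over a K range plus the Evanno delta-K table."""

    runs: list[RunResult]
    delta_k: pd.DataFrame
    best_k: int
    best_run: RunResult

    def summary(self) -> str:
        lines = ["Admixture battery summary", "=" * 25]
        lines.append(
            self.delta_k.to_string(
                float_format=lambda v: f"{v:.3f}", na_rep="-"
            )
        )
        lines.append(f"best K (max delta-K): {self.best_k}")
        lines.append(
            f"retained run: K={self.best_run.K}, run {self.best_run.run_index}, "
            f"lnP(D) = {self.best_run.ln_p_d:.1f}"
        )
        return "\n".join(lines)


def evanno_table(lnp_by_k: dict[int, Sequence[float]]) -> pd.DataFrame:
    """Mean/sd of lnP(D) per K and the Evanno delta-K for interior K.

    delta-K is NaN at the edges of the K range and where the across-run sd
    is zero.
    """
    ks = sorted(lnp_by_k)
    mean = {k: float(np.mean(lnp_by_k[k])) for k in ks}
    sd = {k: float(np.std(lnp_by_k[k], ddof=1)) if len(lnp_by_k[k]) > 1 else 0.0
          for k in ks}
    rows = []
    for k in ks:
        dk = np.nan
        if k - 1 in mean and k + 1 in mean and sd[k] > 0:
            dk = abs(mean[k + 1] - 2 * mean[k] + mean[k - 1]) / sd[k]
        rows.append(
            {"K": k, "mean_lnP": mean[k], "sd_lnP": sd[k],
             "n_runs": len(lnp_by_k[k]), "delta_K": dk}
        )
    return pd.DataFrame(rows).set_index("K")


def assign_membership(
    q: pd.DataFrame | np.ndarray,
    threshold: float = 0.75,
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Assign each accession to its majority cluster when the inferred
    ancestry strictly exceeds *threshold*, else ADMIXED.

    Returns a table with columns ``group`` (e.g. ``G3`` or ``ADMIXED``),
    ``max_q`` and ``cluster`` (0-based argmax).  ``.attrs["group_sizes"]``
    and ``.attrs["admixed_fraction"]`` summarise the assignment.
    """
    if isinstance(q, pd.DataFrame):
        values = q.to_numpy(float)
        index = list(q.index)
    else:
        values = np.asarray(q, float)
        index = list(labels) if labels is not None else list(range(len(values)))
    if not np.allclose(values.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("Q rows must sum to 1")
    arg = values.argmax(axis=1)
    mx = values.max(axis=1)
    group = np.where(mx > threshold, [f"G{a + 1}" for a in arg], ADMIXED)
    out = pd.DataFrame(
        {"group": group, "max_q": mx, "cluster": arg}, index=index
    )
    out.attrs["group_sizes"] = out["group"].value_counts().to_dict()
    out.attrs["admixed_fraction"] = float((out["group"] == ADMIXED).mean())
    return out


class AdmixtureModel:
    """Admixture-model clustering of a genotype panel.

    Parameters
    ----------
    genotypes
        The diploid SSR panel; allele sizes are recoded internally.
    config
        MCMC settings; defaults to production scale, use
        ``SamplerConfig.desk()`` for quick runs.
    """

    def __init__(
        self, genotypes: GenotypeMatrix, config: SamplerConfig | None = None
    ) -> None:
        self.genotypes = genotypes.drop_all_missing()
        self.config = config or SamplerConfig()
        self._coded, self._n_alleles = _recode(self.genotypes)
        if self.genotypes.n_accessions == 0:
            raise ValueError("empty genotype panel")

    def fit(self, K: int, seed: int = 0, run_index: int = 0) -> RunResult:
        """Run the Gibbs sampler at one K with one seed."""
        if K < 1:
            raise ValueError("K must be >= 1")
        n_mlgs = len(
            {tuple(np.sort(row, axis=1).ravel()) for row in self._coded}
        )
        if K > n_mlgs:
            import warnings

            warnings.warn(
                f"K={K} exceeds the number of distinct genotypes ({n_mlgs})",
                stacklevel=2,
            )
        cfg = self.config
        q_mean, p_mean, ll, alpha = _gibbs_core(
            self._coded,
            self._n_alleles,
            K,
            cfg.burn_in,
            cfg.mcmc_iters,
            cfg.lam,
            cfg.alpha,
            cfg.infer_alpha,
            int(seed) % (2**31 - 1),
        )
        ln_p_d = float(ll.mean() - ll.var() / 2.0)
        q = pd.DataFrame(
            q_mean,
            index=self.genotypes.accession_ids,
            columns=[f"Q{k + 1}" for k in range(K)],
        )
        return RunResult(K, run_index, ln_p_d, q, p_mean, ll, alpha)

    def fit_battery(
        self, k_range: Sequence[int] = range(1, 21), seed: int = 0
    ) -> BatteryResult:
        """Run ``config.n_runs`` independent chains per K and select K by
        the maximum Evanno delta-K; the maximum-likelihood run at the
        selected K is retained for membership assignment."""
        runs: list[RunResult] = []
        lnp: dict[int, list[float]] = {}
        for K in k_range:
            lnp[K] = []
            for r in range(self.config.n_runs):
                sub_seed = (int(seed) * 7919 + 1009 * K + r) % (2**31 - 1)
                res = self.fit(K, seed=sub_seed, run_index=r)
                runs.append(res)
                lnp[K].append(res.ln_p_d)
        table = evanno_table(lnp)
        if table["delta_K"].notna().any():
            best_k = int(table["delta_K"].idxmax())
        else:
            best_k = int(table["mean_lnP"].idxmax())
        candidates = [r for r in runs if r.K == best_k]
        best_run = max(candidates, key=lambda r: r.ln_p_d)
        return BatteryResult(runs, table, best_k, best_run)
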