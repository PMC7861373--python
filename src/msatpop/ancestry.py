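"""Bayesian admixture inference with inbreeding, and its post-processing.

The generative model is an admixture model extended with a selfing-derived
inbreeding rate, suited to largely-selfing yeasts whose genotypes show a
strong homozygote excess.  For ``N`` diploid individuals typed at ``L``
microsatellite loci with ``K`` ancestral clusters:

* cluster allele frequencies ``p_kl ~ Dirichlet(lambda)`` per locus,
* individual membership ``q_i ~ Dirichlet(alpha)``,
* at each (individual, locus): with probability ``s`` the two allele
  copies are identical by descent — a single origin ``z ~ q_i`` and a
  single allele drawn from ``p_z``, copied to both slots; otherwise the
  two copies draw origins and alleles independently.

``s`` captures the homozygote excess that selfing generations produce; it
is a deliberate single-parameter simplification of samplers that model
the number of selfing generations explicitly.  All latent variables are
Gibbs-sampled; ``s`` has a conjugate Beta full conditional under its
uniform prior; ``alpha`` moves by Metropolis-Hastings on the log scale
with a uniform prior on (0, 10].

Model choice across K uses DIC = D_bar + p_D with
p_D = D_bar - D(theta_bar), i.e. DIC = 2 * D_bar - D(theta_bar), where
deviance D = -2 log-likelihood is recorded every kept sweep and
theta_bar is the posterior mean of (Q, P, s).

Multiple chains (which suffer label switching) are aligned with a greedy
column-permutation scheme over many random input orders; the similarity
of two aligned runs is G(A, B) = 1 - ||A - B||_F / sqrt(2N) and H is the
mean pairwise G after alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging
import math

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln

from .genotype_io import MISSING, GenotypeTable

logger = logging.getLogger(__name__)


class AncestryError(ValueError):
    pass


def _encode(table: GenotypeTable):
    """Integer-code alleles per locus; missing loci get code -1."""
    N, L = len(table), len(table.loci)
    codes_a = np.full((N, L), -1, dtype=np.int64)
    codes_b = np.full((N, L), -1, dtype=np.int64)
    allele_values: list[np.ndarray] = []
    for j in range(L):
        a = table.alleles[:, j, :]
        ok = a[:, 0] != MISSING
        vals = np.unique(a[ok].ravel())
        allele_values.append(vals)
        lookup = {int(v): k for k, v in enumerate(vals)}
        codes_a[ok, j] = [lookup[int(v)] for v in a[ok, 0]]
        codes_b[ok, j] = [lookup[int(v)] for v in a[ok, 1]]
    return codes_a, codes_b, allele_values


def _sample_rows(rng, probs: np.ndarray) -> np.ndarray:
    """One categorical draw per row of an unnormalized (n, K) matrix."""
    cdf = np.cumsum(probs, axis=1)
    u = rng.random(probs.shape[0]) * cdf[:, -1]
    return (u[:, None] > cdf).sum(axis=1)


@dataclass
class AncestryMatrix:
    """Posterior summaries of one admixture chain."""

    ids: list[str]
    K: int
    Q: np.ndarray                     # N x K posterior mean memberships
    P: list[np.ndarray]               # per locus: K x n_alleles posterior mean
    allele_values: list[np.ndarray]   # per locus: allele repeat counts
    loci: list[str]
    s: float                          # posterior mean inbreeding rate
    alpha: float
    deviance: np.ndarray              # trace, one entry per kept sweep
    deviance_at_means: float
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.Q, index=self.ids,
                          columns=[f"K{k + 1}" for k in range(self.K)])
        df.index.name = "id"
        return df


def _loglik(codes_a, codes_b, Q, P, s) -> float:
    """Log-likelihood of the observed genotypes given (Q, P, s)."""
    ll = 0.0
    L = codes_a.shape[1]
    for j in range(L):
        ok = codes_a[:, j] >= 0
        if not ok.any():
            continue
        a = codes_a[ok, j]
        b = codes_b[ok, j]
        m_a = (Q[ok] * P[j][:, a].T).sum(axis=1)
        m_b = (Q[ok] * P[j][:, b].T).sum(axis=1)
        hom = a == b
        lik = np.where(hom,
                       s * m_a + (1 - s) * m_a * m_b,
                       (1 - s) * 2.0 * m_a * m_b)
        ll += float(np.log(np.maximum(lik, 1e-300)).sum())
    return ll


def _alpha_loglik(alpha: float, Q: np.ndarray) -> float:
    N, K = Q.shape
    return (N * (gammaln(K * alpha) - K * gammaln(alpha))
            + (alpha - 1.0) * float(np.log(np.maximum(Q, 1e-300)).sum()))


def run_chain(table: GenotypeTable, K: int, n_burnin: int = 5_000,
              n_iter: int = 10_000, seed: int | None = None,
              alpha: float = 1.0, lam: float = 1.0,
              fix_s: float | None = None,
              update_alpha: bool = True) -> AncestryMatrix:
    """Run one MCMC chain of the admixture-with-inbreeding model.

    ``n_burnin`` sweeps are discarded, ``n_iter`` kept.  ``fix_s`` pins
    the inbreeding rate (0 recovers the standard admixture model).
    Desk-scale defaults (5,000 / 10,000) are far below production-scale
    settings (hundreds of thousands of sweeps), which can be passed
    directly for full runs.
    """
    if K < 1:
        raise AncestryError("K must be >= 1")
    if n_burnin < 0 or n_iter <= 0:
        raise AncestryError("iteration counts must be positive")
    n_mlgs = len({tuple(row.ravel()) for row in table.alleles})
    if K > n_mlgs:
        logger.warning("K=%d exceeds the %d distinct MLGs; empty clusters "
                       "are likely", K, n_mlgs)

    rng = np.random.default_rng(seed)
    codes_a, codes_b, allele_values = _encode(table)
    N, L = codes_a.shape
    obs = [np.flatnonzero(codes_a[:, j] >= 0) for j in range(L)]
    n_obs_total = int(sum(len(o) for o in obs))

    # initial state
    Q = rng.dirichlet(np.full(K, 1.0), size=N)
    P = [rng.dirichlet(np.full(len(v), 1.0), size=K) for v in allele_values]
    s = 0.5 if fix_s is None else float(fix_s)
    a_cur = float(alpha)

    Q_sum = np.zeros((N, K))
    P_sum = [np.zeros_like(p) for p in P]
    s_sum = 0.0
    dev = np.empty(n_iter)

    for sweep in range(n_burnin + n_iter):
        counts_q = np.zeros((N, K))
        counts_p = [np.zeros_like(p) for p in P]
        n_ibd = 0
        for j in range(L):
            o = obs[j]
            if len(o) == 0:
                continue
            a = codes_a[o, j]
            b = codes_b[o, j]
            Pj = P[j]
            wa = Q[o] * Pj[:, a].T          # (n_o, K) unnormalized
            wb = Q[o] * Pj[:, b].T
            m_a = wa.sum(axis=1)
            m_b = wb.sum(axis=1)
            hom = a == b
            # IBD indicator (only homozygous loci can be IBD)
            h = np.zeros(len(o), dtype=bool)
            if s > 0 and hom.any():
                p1 = s * m_a[hom]
                p0 = (1 - s) * m_a[hom] * m_b[hom]
                h[hom] = rng.random(hom.sum()) < p1 / (p1 + p0)
            n_ibd += int(h.sum())
            z1 = _sample_rows(rng, wa)
            # IBD rows: single origin z1, single allele draw
            ib = np.flatnonzero(h)
            ni = np.flatnonzero(~h)
            np.add.at(counts_q, (o[ib], z1[ib]), 1.0)
            np.add.at(counts_p[j], (z1[ib], a[ib]), 1.0)
            # non-IBD rows: independent origins for both copies
            z2 = _sample_rows(rng, wb[ni])
            np.add.at(counts_q, (o[ni], z1[ni]), 1.0)
            np.add.at(counts_q, (o[ni], z2), 1.0)
            np.add.at(counts_p[j], (z1[ni], a[ni]), 1.0)
            np.add.at(counts_p[j], (z2, b[ni]), 1.0)

        # conjugate updates
        g = rng.gamma(a_cur + counts_q)
        Q = g / g.sum(axis=1, keepdims=True)
        for j in range(L):
            g = rng.gamma(lam + counts_p[j])
            P[j] = g / g.sum(axis=1, keepdims=True)
        if fix_s is None:
            s = rng.beta(1 + n_ibd, 1 + n_obs_total - n_ibd)
        if update_alpha and K > 1:
            prop = a_cur * math.exp(0.3 * rng.standard_normal())
            if 0 < prop <= 10.0:
                log_r = (_alpha_loglik(prop, Q) - _alpha_loglik(a_cur, Q)
                         + math.log(prop) - math.log(a_cur))  # log-scale move
                if math.log(rng.random()) < log_r:
                    a_cur = prop

        if sweep >= n_burnin:
            k = sweep - n_burnin
            Q_sum += Q
            for j in range(L):
                P_sum[j] += P[j]
            s_sum += s
            dev[k] = -2.0 * _loglik(codes_a, codes_b, Q, P, s)

    Q_bar = Q_sum / n_iter
    P_bar = [p / n_iter for p in P_sum]
    s_bar = s_sum / n_iter
    d_at_means = -2.0 * _loglik(codes_a, codes_b, Q_bar, P_bar, s_bar)
    return AncestryMatrix(list(table.ids), K, Q_bar, P_bar, allele_values,
                          list(table.loci), s_bar, a_cur, dev, d_at_means,
                          seed)


def dic(chain: AncestryMatrix) -> float:
    """Deviance information criterion 2 * D_bar - D(theta_bar)."""
    if chain.deviance.size == 0:
        raise AncestryError("empty deviance trace")
    return float(2.0 * chain.deviance.mean() - chain.deviance_at_means)


def dic_table(runs: dict[int, list[AncestryMatrix]]) -> pd.DataFrame:
    """DIC per (K, chain), with per-K minima and plateau flags.

    A plateau is flagged where adding a cluster improves the per-K best
    DIC by less than 2 (a conventional 'no better' margin) — exposing the
    'minor minimum plateau' pattern to the user rather than auto-picking.
    """
    rows = []
    for K in sorted(runs):
        for c, chain in enumerate(runs[K]):
            rows.append({"K": K, "chain": c, "DIC": dic(chain)})
    df = pd.DataFrame(rows)
    best = df.groupby("K")["DIC"].min()
    plateau = {K: bool(K > best.index.min()
                       and best.get(K - 1, np.inf) - best[K] < 2.0)
               for K in best.index}
    df["plateau_at_K"] = df["K"].map(plateau)
    return df


def _g_similarity(A: np.ndarray, B: np.ndarray) -> float:
    n = A.shape[0]
    return 1.0 - float(np.linalg.norm(A - B)) / math.sqrt(2.0 * n)


def _best_permutation(A: np.ndarray, refs: list[np.ndarray]) -> np.ndarray:
    """Column permutation of A minimizing summed squared distance to refs."""
    K = A.shape[1]
    cost = np.zeros((K, K))
    for B in refs:
        for jcol in range(K):
            cost[jcol] += ((A[:, jcol][:, None] - B) ** 2).sum(axis=0)
    _, assign = linear_sum_assignment(cost)
    out = np.empty(K, dtype=int)
    out[assign] = np.arange(K)  # out[k] = source column for target slot k
    return out


def align_runs(Q_list: list[np.ndarray], n_random_orders: int = 100,
               seed: int | None = None):
    """Greedy label alignment of replicate Q matrices.

    Runs are added one at a time (in ``n_random_orders`` randomized
    orders); each is column-permuted to best match the running aligned
    set; the order with the highest mean pairwise similarity H is kept.
    Returns ``(aligned list, consensus Q, H)``.
    """
    shapes = {q.shape for q in Q_list}
    if len(shapes) != 1:
        raise AncestryError(f"Q matrices differ in shape: {shapes}")
    R = len(Q_list)
    if R == 1:
        return [Q_list[0].copy()], Q_list[0].copy(), 1.0
    rng = np.random.default_rng(seed)
    best_H = -np.inf
    best_aligned = None
    for trial in range(max(1, n_random_orders)):
        order = rng.permutation(R) if trial else np.arange(R)
        aligned = {int(order[0]): Q_list[order[0]].copy()}
        for r in order[1:]:
            perm = _best_permutation(Q_list[r], list(aligned.values()))
            aligned[int(r)] = Q_list[r][:, perm]
        al = [aligned[r] for r in range(R)]
        sims = [_g_similarity(al[i], al[j])
                for i in range(R) for j in range(i + 1, R)]
        H = float(np.mean(sims))
        if H > best_H:
            best_H, best_aligned = H, al
    consensus = np.mean(best_aligned, axis=0)
    return best_aligned, consensus, best_H


def dominant_ancestor(Q: np.ndarray, cutoff: float = 0.75) -> list[int | None]:
    """Arg-max cluster per individual if its coefficient >= cutoff, else
    None (no dominant inferred ancestor)."""
    Q = np.asarray(Q, dtype=float)
    out: list[int | None] = []
    for row in Q:
        k = int(np.argmax(row))
        out.append(k if row[k] >= cutoff else None)
    return out


def structure_r2(Q: np.ndarray, predefined_pops, n_perm: int = 999,
                 seed: int | None = None):
    """How much of the ancestry-profile variance predefined populations
    explain: R^2 = 1 - SSW/SST on Q rows, with a label-permutation
    p-value and per-population leave-one-out contributions.
    """
    Q = np.asarray(Q, dtype=float)
    pops = np.asarray(predefined_pops)
    if len(pops) != Q.shape[0]:
        raise AncestryError("population labels do not match Q")
    uniq = pd.unique(pops)
    if len(uniq) < 2:
        raise AncestryError("need at least two predefined populations")
    for u in uniq:
        if (pops == u).sum() == 0:
            raise AncestryError(f"empty population {u!r}")

    def r2_of(Qm, labels):
        grand = Qm.mean(axis=0)
        sst = float(((Qm - grand) ** 2).sum())
        ssw = 0.0
        for u in pd.unique(labels):
            sub = Qm[labels == u]
            ssw += float(((sub - sub.mean(axis=0)) ** 2).sum())
        return 1.0 - ssw / sst if sst > 0 else 0.0

    r2 = r2_of(Q, pops)
    rng = np.random.default_rng(seed)
    count = sum(r2_of(Q, rng.permutation(pops)) >= r2 for _ in range(n_perm))
    p = (1 + count) / (1 + n_perm)

    contributions = {}
    for u in uniq:
        keep = pops != u
        if len(pd.unique(pops[keep])) >= 2:
            contributions[str(u)] = r2 - r2_of(Q[keep], pops[keep])
        else:
            contributions[str(u)] = float("nan")
    return r2, p, contributions


def write_q_matrix(chain_or_Q, ids, pops, path) -> None:
    """Export a Q matrix in the one-row-per-individual text layout
    (id, predefined population, membership coefficients) accepted by
    standard ancestry-plotting tools."""
    Q = chain_or_Q.Q if isinstance(chain_or_Q, AncestryMatrix) else chain_or_Q
    with open(path, "w", encoding="utf-8") as fh:
        for i, (iid, pop) in enumerate(zip(ids, pops)):
            coeffs = " ".join(f"{v:.4f}" for v in Q[i])
            fh.write(f"{iid} {pop} : {coeffs}\n")
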