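"""Synthetic microsatellite isolate datasets with known ground truth.

The generator emulates the statistical structure of a highly-selfing
yeast population sampled from barrel fermentations: 11 microsatellite
loci with 3-18 alleles each, ~100 strains with a handful of dominant
strains, strong homozygote excess (selfing rate ~0.8, giving realized
F_IS around 0.7), two weakly differentiated vineyard subpopulations
(F_ST on the order of 0.01 arising from compositional differences), and
per-sample isolate counts of ~47 rarefied to 32 downstream.

Strains are founded by drawing an admixture profile per strain and
genotypes from K ancestral allele-frequency clusters with probability-s
identical-by-descent allele copies; isolates inherit their strain's
founder MLG plus rare single-step (+/-1 repeat) mutations, keeping
within-strain Bruvo distances far below the delineation threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genotype_io import DEFAULT_LOCI, GenotypeTable


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    seed: int = 0
    n_loci: int = 11
    alleles_per_locus: tuple[int, int] = (3, 18)
    K: int = 5
    admixture_alpha: float = 0.2     # small -> strains have dominant ancestors
    selfing: float = 0.8             # IBD probability per locus at founding
    cluster_divergence: float = 1.0  # Dirichlet concentration scale; smaller
                                     # means more divergent cluster frequencies
    n_strains: int = 100
    n_dominant: int = 4
    dominant_share: float = 0.58     # total abundance mass of dominant strains
    geometric_ratio: float = 0.98    # decay of minor-strain abundances
    vineyards: tuple[str, ...] = ("V2", "V8")
    n_barrels: int = 3
    stages: tuple[str, ...] = ("early", "mid", "late")
    isolates_per_sample: int = 47
    mutation_rate: float = 0.005     # per allele copy per locus, +/-1 repeat
    min_founder_distance: float = 0.35  # strains are distinct lineages: keep
                                        # founder MLGs separated in Bruvo space
    vintage: str = "2017"
    identical_vineyards: bool = False  # same strain pool in both vineyards

    def __post_init__(self) -> None:
        if not 0.0 <= self.selfing <= 1.0:
            raise SimulationError("selfing must be in [0, 1]")
        if self.n_dominant > self.n_strains:
            raise SimulationError("abundance law incompatible with n_strains: "
                                  "more dominant strains than strains")
        for v in (self.n_loci, self.K, self.n_strains, self.n_barrels,
                  self.isolates_per_sample):
            if v <= 0:
                raise SimulationError("all counts must be positive")


def study_config(seed: int = 0) -> SimulationConfig:
    """The default study-shaped conditions: 2 vineyards x 3 barrels x
    3 stages, 47 isolates per sample, ~100 strains with 4 dominant,
    K=5 ancestries, selfing 0.8."""
    return SimulationConfig(seed=seed)


@dataclass
class GroundTruth:
    strain_of_isolate: pd.Series        # isolate_id -> true strain index
    strain_q: np.ndarray                # n_strains x K admixture profiles
    cluster_freqs: list[np.ndarray]     # per locus: K x n_alleles
    allele_values: list[np.ndarray]     # per locus: repeat counts
    founder_alleles: np.ndarray         # n_strains x L x 2 repeat counts
    abundance: pd.DataFrame             # realized counts, sample x strain
    weights: pd.DataFrame               # sampling weights, vineyard x strain
    config: SimulationConfig = field(repr=False, default=None)


def _strain_weights(cfg: SimulationConfig, rng) -> pd.DataFrame:
    """Per-vineyard strain sampling weights.

    Dominant strains: the first two are shared across vineyards; the
    remaining dominant strains alternate as vineyard specialists (strong
    at home, rare away), mirroring vineyard-specific dominant strains.
    Minor strains decay geometrically, with mild vineyard-specific jitter.
    """
    n, nd = cfg.n_strains, cfg.n_dominant
    minor = np.array([cfg.geometric_ratio ** i for i in range(n - nd)])
    minor = minor / minor.sum() * (1.0 - cfg.dominant_share)
    weights = {}
    for vi, v in enumerate(cfg.vineyards):
        dom = np.zeros(nd)
        shared = min(2, nd)
        if shared:
            dom[:shared] = cfg.dominant_share * 0.55 / shared
        spec_mass = cfg.dominant_share - dom.sum()
        specialists = nd - shared
        if specialists:
            if cfg.identical_vineyards:
                dom[shared:] = spec_mass / specialists
            else:
                home = np.array([(k % len(cfg.vineyards)) == vi
                                 for k in range(specialists)])
                dom[shared:][home] = spec_mass / max(1, home.sum())
                dom[shared:][~home] = 0.003
        # renormalize dominant block to its share
        if dom.sum() > 0:
            dom = dom / dom.sum() * cfg.dominant_share
        if cfg.identical_vineyards:
            jitter = minor
        else:
            jitter = rng.dirichlet(minor * 4000 + 1e-3) * minor.sum()
        w = np.concatenate([dom, jitter])
        weights[v] = w / w.sum()
    return pd.DataFrame(weights).T  # vineyard x strain


def simulate_population(cfg: SimulationConfig):
    """Generate an isolate table and its ground truth.

    Returns ``(IsolateTable as GenotypeTable, GroundTruth)``; byte-stable
    under a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    L, K = cfg.n_loci, cfg.K
    base = list(DEFAULT_LOCI)
    loci = base[:L] if L <= len(base) \
        else base + [f"X{j + 1}" for j in range(L - len(base))]

    lo, hi = cfg.alleles_per_locus
    n_alleles = rng.integers(lo, hi + 1, size=L)
    bases = rng.integers(8, 25, size=L)
    allele_values = [np.arange(b, b + m) for b, m in zip(bases, n_alleles)]

    # ancestral cluster allele frequencies; smaller concentration -> more
    # divergent clusters
    conc = cfg.cluster_divergence
    cluster_freqs = [rng.dirichlet(np.full(m, conc), size=K)
                     for m in n_alleles]

    # strain founders: admixture profile + IBD-aware genotype draw
    strain_q = rng.dirichlet(np.full(K, cfg.admixture_alpha),
                             size=cfg.n_strains)
    founder = np.empty((cfg.n_strains, L, 2), dtype=np.int64)

    def draw_founder(q):
        g = np.empty((L, 2), dtype=np.int64)
        for j in range(L):
            mix = q @ cluster_freqs[j]
            if rng.random() < cfg.selfing:
                a = rng.choice(allele_values[j], p=mix)
                g[j] = (a, a)
            else:
                g[j] = np.sort(rng.choice(allele_values[j], size=2, p=mix))
        return g

    def min_dist(g, others):
        if not len(others):
            return np.inf
        from .bruvo import genotype_locus_distance
        best = np.inf
        for o in others:
            d = np.mean([genotype_locus_distance(tuple(g[j]), tuple(o[j]))
                         for j in range(L)])
            best = min(best, d)
        return best

    accepted: list[np.ndarray] = []
    for i in range(cfg.n_strains):
        for _ in range(200):  # rejection: founders are distinct lineages
            g = draw_founder(strain_q[i])
            if min_dist(g, accepted) >= cfg.min_founder_distance:
                break
        else:
            raise SimulationError(
                "could not place founders at the requested separation; "
                "lower n_strains or min_founder_distance"
            )
        accepted.append(g)
        founder[i] = g

    weights = _strain_weights(cfg, rng)

    ids, meta_rows, alleles, truth_strain = [], [], [], []
    counts = {}
    for v in cfg.vineyards:
        w = weights.loc[v].to_numpy()
        for b in range(1, cfg.n_barrels + 1):
            for stage in cfg.stages:
                sample = f"{v}|B{b}|{stage}"
                drawn = rng.choice(cfg.n_strains, size=cfg.isolates_per_sample,
                                   p=w)
                counts[sample] = np.bincount(drawn, minlength=cfg.n_strains)
                for k, strain in enumerate(drawn):
                    iid = f"{sample}|iso{k:02d}"
                    g = founder[strain].copy()
                    if cfg.mutation_rate > 0:
                        mut = rng.random((L, 2)) < cfg.mutation_rate
                        step = rng.choice([-1, 1], size=(L, 2))
                        g = np.maximum(g + mut * step, 0)
                    ids.append(iid)
                    meta_rows.append({"isolate_id": iid,
                                      "vintage": cfg.vintage,
                                      "vineyard": v, "barrel": f"B{b}",
                                      "stage": stage})
                    alleles.append(np.sort(g, axis=1))
                    truth_strain.append(int(strain))

    table = GenotypeTable(ids, loci, np.stack(alleles),
                          pd.DataFrame(meta_rows))
    abundance = pd.DataFrame(counts).T
    abundance.index.name = "sample"
    truth = GroundTruth(pd.Series(truth_strain, index=ids,
                                  name="true_strain"),
                        strain_q, cluster_freqs, allele_values, founder,
                        abundance, weights, cfg)
    return table, truth


def adjusted_rand_index(labels_a, labels_b) -> float:
    from sklearn.metrics import adjusted_rand_score
    return float(adjusted_rand_score(labels_a, labels_b))


def recovery_report(truth: GroundTruth, inferred) -> dict:
    """Compare an inference result against the generating truth.

    * strain assignment -> adjusted Rand index of the two partitions;
    * ancestry Q matrix (per-strain) -> mean absolute error after the
      best column permutation;
    * dict of statistics -> (estimate - truth) table.
    """
    from .ancestry import AncestryMatrix, _best_permutation
    from .delineation import StrainAssignment

    if isinstance(inferred, StrainAssignment):
        ids = list(inferred.isolate_to_strain)
        missing = set(ids) - set(truth.strain_of_isolate.index)
        if missing:
            raise SimulationError(f"unknown isolate id(s): {sorted(missing)}")
        true_labels = truth.strain_of_isolate.loc[ids].to_numpy()
        inf_labels = np.array([inferred.isolate_to_strain[i] for i in ids])
        return {"ari": adjusted_rand_index(true_labels, inf_labels),
                "n_strains_true": int(len(np.unique(true_labels))),
                "n_strains_inferred": int(len(np.unique(inf_labels)))}
    if isinstance(inferred, AncestryMatrix):
        if inferred.Q.shape != truth.strain_q.shape:
            raise SimulationError("Q shape does not match truth")
        perm = _best_permutation(inferred.Q, [truth.strain_q])
        err = float(np.mean(np.abs(inferred.Q[:, perm] - truth.strain_q)))
        return {"q_mae": err}
    if isinstance(inferred, dict):
        return {k: {"estimate": v[0], "truth": v[1], "error": v[0] - v[1]}
                for k, v in inferred.items()}
    raise SimulationError(f"unsupported inference type {type(inferred)!r}")
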