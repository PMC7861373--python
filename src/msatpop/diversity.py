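"""Composition, diversity, ordination and permutation tests.

Operates on sample x entity abundance tables (strain counts per
fermentation sample, or taxon counts).  Diversity indices are Simpson's
index of diversity (1 - D) and Shannon's H (natural log).  Sample
dissimilarity is Bray-Curtis on untransformed abundances; ordination is
classical PCoA (Gower double-centering, no negative-eigenvalue
correction); group location is tested with one-way PERMANOVA and group
dispersion with PERMDISP, both with the (1 + count) / (1 + n_perm)
permutation p-value convention, so 999 permutations give a p-value floor
of 0.001.

PERMANOVA here is the one-way design only; repeated-measures structure
(the same barrel sampled over fermentation stages) is not modelled, so
ordination should be inspected alongside any significant test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .bruvo import DistanceMatrix
from .delineation import StrainAssignment, sample_key
from .genotype_io import GenotypeTable


class DiversityError(ValueError):
    pass


def strain_abundance(table: GenotypeTable, assignment: StrainAssignment,
                     names: dict[int, str] | None = None) -> pd.DataFrame:
    """Sample x strain count table from a strain assignment.

    Rows are (vineyard, barrel, stage) samples; columns strain names (or
    numeric strain ids if ``names`` is None).
    """
    keys = sample_key(table.metadata)
    strains = [assignment.isolate_to_strain[i] for i in table.ids]
    if names:
        strains = [names[s] for s in strains]
    df = pd.crosstab(keys, pd.Series(strains, index=keys.index))
    df.index.name = "sample"
    df.columns.name = "entity"
    return df


def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Row-normalize counts to proportions; errors on an all-zero row."""
    sums = counts.sum(axis=1)
    if (sums <= 0).any():
        bad = counts.index[sums <= 0].tolist()
        raise DiversityError(f"zero row sum for sample(s): {bad}")
    return counts.div(sums, axis=0)


def simpson_diversity(p) -> float:
    """Simpson's index of diversity 1 - D = 1 - sum(p_i^2)."""
    p = np.asarray(p, dtype=float)
    return float(1.0 - np.sum(p ** 2))


def shannon_diversity(p) -> float:
    """Shannon's H = -sum(p_i ln p_i), natural log, 0 ln 0 := 0."""
    p = np.asarray(p, dtype=float)
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


def diversity_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample richness, Simpson (1 - D) and Shannon (H)."""
    props = relative_abundance(counts)
    return pd.DataFrame({
        "richness": (counts > 0).sum(axis=1),
        "simpson": [simpson_diversity(r) for _, r in props.iterrows()],
        "shannon": [shannon_diversity(r) for _, r in props.iterrows()],
    }, index=counts.index)


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) on raw abundances."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    denom = np.sum(x + y)
    if denom == 0:
        raise DiversityError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.sum(np.abs(x - y)) / denom)


def bray_curtis_matrix(counts: pd.DataFrame) -> DistanceMatrix:
    if (counts.sum(axis=1) == 0).any():
        raise DiversityError("all-zero sample row in abundance table")
    vals = squareform(pdist(counts.to_numpy(dtype=float), metric="braycurtis"))
    return DistanceMatrix([str(i) for i in counts.index], vals)


@dataclass
class PCoAResult:
    coordinates: np.ndarray          # n x n_pos real axes, scaled by sqrt(l)
    eigenvalues: np.ndarray          # all eigenvalues, descending
    proportion_explained: np.ndarray  # lambda_k / sum positive lambda
    imag_coordinates: np.ndarray     # axes for negative eigenvalues
    labels: list[str]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCo{k + 1}" for k in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.labels, columns=cols)


def pcoa(dm: DistanceMatrix) -> PCoAResult:
    """Classical principal coordinates analysis.

    Gower double-centering of -0.5 * D^2 followed by eigendecomposition;
    axes ordered by decreasing eigenvalue; variance fractions are over
    positive eigenvalues only.  Negative eigenvalues (non-Euclidean input)
    are reported and kept as imaginary axes — no Cailliez/Lingoes
    correction is applied.
    """
    D = dm.values
    n = D.shape[0]
    A = -0.5 * D ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    B = (B + B.T) / 2.0
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-10, 1e-10 * abs(evals).max() if n else 0)
    pos = evals > tol
    neg = evals < -tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    imag = evecs[:, neg] * np.sqrt(-evals[neg])
    total_pos = evals[pos].sum()
    prop = evals[pos] / total_pos if total_pos > 0 else evals[pos]
    return PCoAResult(coords, evals, prop, imag, list(dm.labels))


@dataclass
class PermutationTestResult:
    statistic: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: int | None
    method: str

    def to_dict(self) -> dict:
        return {"statistic": self.statistic, "r_squared": self.r_squared,
                "p_value": self.p_value,
                "n_permutations": self.n_permutations, "seed": self.seed,
                "method": self.method}


def _check_groups(groups: np.ndarray) -> list[np.ndarray]:
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise DiversityError("need at least two groups")
    masks = [np.asarray(groups) == g for g in uniq]
    for g, m in zip(uniq, masks):
        if m.sum() < 2:
            raise DiversityError(f"group {g!r} has fewer than two members")
    return masks


def _permanova_f(d2: np.ndarray, codes: np.ndarray, n_groups: int):
    """Pseudo-F and R^2 for one labelling (codes in 0..n_groups-1)."""
    n = d2.shape[0]
    sst = d2[np.triu_indices(n, 1)].sum() / n
    ssw = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        ng = len(idx)
        sub = d2[np.ix_(idx, idx)]
        ssw += sub[np.triu_indices(ng, 1)].sum() / ng
    ssa = sst - ssw
    a = n_groups
    if ssw == 0:  # perfectly separated groups
        return np.inf, 1.0
    f = (ssa / (a - 1)) / (ssw / (n - a))
    return f, ssa / sst


def permanova(dm: DistanceMatrix, groups, n_perm: int = 999,
              seed: int | None = None) -> PermutationTestResult:
    """One-way PERMANOVA on a dissimilarity matrix.

    SST = (1/N) sum_{i<j} d_ij^2; SSW = sum_g (1/n_g) sum_{i<j in g}
    d_ij^2; pseudo-F = (SSA/(a-1)) / (SSW/(N-a)).  The p-value permutes
    the raw group labels: p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    groups = np.asarray(groups)
    if len(groups) != len(dm):
        raise DiversityError("group labels do not match distance matrix")
    _check_groups(groups)
    codes, uniq = pd.factorize(groups)
    a = len(uniq)
    d2 = dm.values ** 2
    f_obs, r2 = _permanova_f(d2, codes, a)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        f_p, _ = _permanova_f(d2, rng.permutation(codes), a)
        if f_p >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermutationTestResult(f_obs, r2, p, n_perm, seed, "PERMANOVA")


def _anova_f(values: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = len(values)
    grand = values.mean()
    ssb = 0.0
    ssw = 0.0
    for g in range(n_groups):
        v = values[codes == g]
        ssb += len(v) * (v.mean() - grand) ** 2
        ssw += ((v - v.mean()) ** 2).sum()
    return (ssb / (n_groups - 1)) / (ssw / (n - n_groups))


def centroid_distances(dm: DistanceMatrix, groups) -> np.ndarray:
    """Distance of each sample to its group centroid in PCoA space.

    The embedding keeps both real and imaginary axes; squared imaginary
    components subtract from squared real ones (clamped at zero), as in
    the deviation-from-centroid dispersion analysis.
    """
    groups = np.asarray(groups)
    res = pcoa(dm)
    codes, uniq = pd.factorize(groups)
    out = np.empty(len(groups))
    for g in range(len(uniq)):
        idx = codes == g
        c_re = res.coordinates[idx].mean(axis=0)
        c_im = res.imag_coordinates[idx].mean(axis=0) \
            if res.imag_coordinates.size else np.zeros(0)
        d2_re = ((res.coordinates[idx] - c_re) ** 2).sum(axis=1)
        d2_im = (((res.imag_coordinates[idx] - c_im) ** 2).sum(axis=1)
                 if res.imag_coordinates.size else 0.0)
        out[idx] = np.sqrt(np.maximum(d2_re - d2_im, 0.0))
    return out


def permdisp(dm: DistanceMatrix, groups, n_perm: int = 999,
             seed: int | None = None) -> PermutationTestResult:
    """Homogeneity of multivariate dispersions (deviation from centroid).

    One-way ANOVA F on the centroid distances; the permutation p-value
    permutes the residuals from the group means.
    """
    groups = np.asarray(groups)
    if len(groups) != len(dm):
        raise DiversityError("group labels do not match distance matrix")
    _check_groups(groups)
    codes, uniq = pd.factorize(groups)
    a = len(uniq)
    dist = centroid_distances(dm, groups)
    f_obs = _anova_f(dist, codes, a)

    means = np.array([dist[codes == g].mean() for g in range(a)])
    resid = dist - means[codes]
    grand = dist.mean()
    ssb = sum((codes == g).sum() * (m - grand) ** 2
              for g, m in enumerate(means))
    sst = ((dist - grand) ** 2).sum()
    r2 = ssb / sst if sst > 0 else 0.0

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        f_p = _anova_f(rng.permutation(resid), codes, a)
        if f_p >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermutationTestResult(f_obs, r2, p, n_perm, seed, "PERMDISP")
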