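"""Collapsing isolate multilocus genotypes into strains.

Isolates whose MLGs differ only by slight allele-size differences (e.g.
single-step mutations or scoring noise) are collapsed into one strain by
agglomerative clustering on Bruvo distances, cut at a genetic-distance
threshold: merging continues while the inter-cluster linkage distance is
strictly below the threshold.  At threshold 0 every unique MLG is its own
strain; at threshold 1 all MLGs collapse into a single strain.  The
default linkage is farthest-neighbour (complete).

When the pairwise-distance histogram is not clearly bimodal, a threshold
can be suggested as the midpoint of the largest gap between consecutive
critical linkage values — the distance values at which the strain count
actually changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .bruvo import DistanceMatrix, genotype_distance
from .genotype_io import GenotypeTable

logger = logging.getLogger(__name__)

_LINKAGE = {"farthest": "complete", "nearest": "single", "average": "average"}


class DelineationError(ValueError):
    pass


@dataclass
class StrainAssignment:
    """Result of collapsing MLGs at a distance threshold."""

    isolate_to_strain: dict[str, int]
    representatives: dict[int, str]  # strain id -> representative isolate id
    threshold: float
    algorithm: str
    representative_genotypes: dict[int, dict] = field(default_factory=dict)

    @property
    def n_strains(self) -> int:
        return len(self.representatives)

    def members(self, strain: int) -> list[str]:
        return [i for i, s in self.isolate_to_strain.items() if s == strain]

    def labels_for(self, ids: list[str]) -> np.ndarray:
        return np.array([self.isolate_to_strain[i] for i in ids])

    def to_frame(self, metadata: pd.DataFrame | None = None,
                 ids: list[str] | None = None) -> pd.DataFrame:
        ids = ids if ids is not None else list(self.isolate_to_strain)
        df = pd.DataFrame({"isolate_id": ids,
                           "strain_id": [self.isolate_to_strain[i]
                                         for i in ids]})
        if metadata is not None and len(metadata):
            df = pd.concat([df, metadata.reset_index(drop=True)
                            .drop(columns=["isolate_id"], errors="ignore")],
                           axis=1)
        return df


def _linkage_matrix(dm: DistanceMatrix, algorithm: str) -> np.ndarray:
    if algorithm not in _LINKAGE:
        raise DelineationError(
            f"unknown algorithm {algorithm!r}; use one of {sorted(_LINKAGE)}"
        )
    return linkage(squareform(dm.values, checks=False),
                   method=_LINKAGE[algorithm])


def _cut_strict(Z: np.ndarray, n: int, threshold: float) -> np.ndarray:
    """Flat clusters from merges with linkage height strictly < threshold."""
    parent = list(range(2 * n - 1))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for k, (i, j, h, _) in enumerate(Z):
        if h < threshold:
            node = n + k
            parent[find(int(i))] = node
            parent[find(int(j))] = node
    roots = [find(i) for i in range(n)]
    # strain ids by order of first member appearance
    order: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, r in enumerate(roots):
        if r not in order:
            order[r] = len(order)
        out[i] = order[r]
    return out


def collapse_mlgs(dm: DistanceMatrix, threshold: float,
                  algorithm: str = "farthest",
                  table: GenotypeTable | None = None) -> StrainAssignment:
    """Agglomerate isolates into strains at a Bruvo-distance threshold.

    Strain ids are assigned deterministically by order of first member
    appearance in ``dm.labels``.  The representative of each strain is
    the member with minimal summed distance to the other members, ties
    broken by lowest isolate id.  Passing the genotype ``table`` also
    records each representative's MLG.
    """
    if not 0.0 <= threshold <= 1.0:
        raise DelineationError(f"threshold must be in [0, 1], got {threshold}")
    n = len(dm)
    if threshold == 0.0:
        # strict < never merges; equal MLGs (distance 0) must still collapse
        labels = _cut_strict(_linkage_matrix(dm, algorithm), n, 1e-300)
    else:
        labels = _cut_strict(_linkage_matrix(dm, algorithm), n, threshold)

    iso2strain = {dm.labels[i]: int(labels[i]) for i in range(n)}
    reps: dict[int, str] = {}
    for s in sorted(set(labels.tolist())):
        member_idx = np.flatnonzero(labels == s)
        sub = dm.values[np.ix_(member_idx, member_idx)].sum(axis=1)
        best = min(range(len(member_idx)),
                   key=lambda k: (sub[k], dm.labels[member_idx[k]]))
        reps[int(s)] = dm.labels[member_idx[best]]

    rep_geno = {}
    if table is not None:
        pos = {iid: i for i, iid in enumerate(table.ids)}
        rep_geno = {s: table.genotype(pos[r]) for s, r in reps.items()}
    return StrainAssignment(iso2strain, reps, threshold, algorithm, rep_geno)


@dataclass
class ThresholdScan:
    """Strain counts as a step function of the collapsing threshold."""

    critical_values: np.ndarray     # sorted unique linkage heights
    n_strains: np.ndarray           # strains once merges at h[k] are applied
    hist_counts: np.ndarray         # pairwise-distance histogram
    hist_edges: np.ndarray
    algorithm: str

    def n_strains_at(self, threshold: float) -> int:
        # merges applied strictly below the threshold
        n_total = len(self._heights) + 1
        merges = int(np.sum(self._heights < threshold))
        return n_total - merges

    _heights: np.ndarray = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.critical_values,
                             "n_strains": self.n_strains})


def threshold_scan(dm: DistanceMatrix,
                   algorithm: str = "farthest",
                   n_bins: int = 20) -> ThresholdScan:
    """Strain count at every critical linkage value, plus the distance
    histogram used for visual threshold choice."""
    Z = _linkage_matrix(dm, algorithm)
    heights = Z[:, 2]
    n = len(dm)
    crit = np.unique(heights)
    # n_strains for a threshold just at/above each critical value
    counts = np.array([n - int(np.sum(heights <= h)) for h in crit])
    hist_counts, hist_edges = np.histogram(dm.condensed(), bins=n_bins,
                                           range=(0.0, 1.0))
    scan = ThresholdScan(crit, counts, hist_counts, hist_edges, algorithm)
    scan._heights = heights
    return scan


def _is_bimodal(counts: np.ndarray) -> bool:
    """Crude dip heuristic: two local maxima separated by a lower bin."""
    nz = counts
    peaks = [k for k in range(len(nz))
             if nz[k] > 0
             and (k == 0 or nz[k] > nz[k - 1])
             and (k == len(nz) - 1 or nz[k] >= nz[k + 1])]
    return len(peaks) >= 2


@dataclass
class ThresholdSuggestion:
    threshold: float
    gap: tuple[float, float]
    histogram_bimodal: bool


def suggest_threshold(dm: DistanceMatrix,
                      algorithm: str = "farthest") -> ThresholdSuggestion:
    """Midpoint of the largest gap between consecutive critical linkage
    values, mirroring the visual largest-gap choice on the threshold scan.
    """
    scan = threshold_scan(dm, algorithm)
    crit = scan.critical_values
    if len(crit) < 2:
        raise DelineationError("no gap: fewer than two distinct linkage "
                               "values")
    gaps = np.diff(crit)
    k = int(np.argmax(gaps))
    lo, hi = float(crit[k]), float(crit[k + 1])
    return ThresholdSuggestion((lo + hi) / 2.0, (lo, hi),
                               _is_bimodal(scan.hist_counts))


def exclude_incomplete(table: GenotypeTable) -> GenotypeTable:
    """Drop isolates with any missing locus (the repeated-partial-amplifier
    exclusion policy); keeps a log of what was removed."""
    keep = np.flatnonzero(~table.missing_mask.any(axis=1))
    dropped = len(table) - len(keep)
    if dropped:
        logger.info("excluding %d isolate(s) with incomplete MLGs", dropped)
    return table.subset(keep)


def match_to_reference(assignment: StrainAssignment,
                       reference: GenotypeTable,
                       threshold: float = 0.3,
                       vintage: str = "2017") -> dict[int, str]:
    """Match each strain's representative MLG to the nearest reference MLG.

    A strain within ``threshold`` of a reference strain takes that
    reference's name; otherwise it is a new strain named
    ``"<vintage> Strain <k>"`` with k serially by strain id order.  Ties
    break by smallest distance, then reference name order (both
    candidates are logged).
    """
    if not assignment.representative_genotypes:
        raise DelineationError(
            "assignment lacks representative genotypes; pass the genotype "
            "table to collapse_mlgs"
        )
    ref_genos = [(reference.ids[i], reference.genotype(i))
                 for i in range(len(reference))]
    out: dict[int, str] = {}
    serial = 0
    for s in sorted(assignment.representatives):
        g = assignment.representative_genotypes[s]
        cand = sorted(
            ((genotype_distance(g, rg), name) for name, rg in ref_genos),
            key=lambda t: (t[0], t[1]),
        )
        best_d, best_name = cand[0]
        if best_d < threshold:
            runners = [n for d, n in cand[1:] if d == best_d]
            if runners:
                logger.info("strain %d ties at distance %.4f: %s",
                            s, best_d, [best_name] + runners)
            out[s] = best_name
        else:
            serial += 1
            out[s] = f"{vintage} Strain {serial}"
    return out


def sample_key(metadata: pd.DataFrame) -> pd.Series:
    """Sample identity of each isolate: one fermentation barrel at one
    stage (vineyard, barrel, stage)."""
    return (metadata["vineyard"].astype(str) + "|"
            + metadata["barrel"].astype(str) + "|"
            + metadata["stage"].astype(str))


def rarefy_isolates(table: GenotypeTable, n: int = 32,
                    seed: int | None = None) -> GenotypeTable:
    """Random subsample of ``n`` isolates per sample, without replacement.

    Equalizes sampling effort across samples before computing strain
    abundances.  Errors naming the sample if any sample holds fewer than
    ``n`` typed isolates.
    """
    rng = np.random.default_rng(seed)
    keys = sample_key(table.metadata)
    keep: list[int] = []
    for key in pd.unique(keys):
        idx = np.flatnonzero((keys == key).to_numpy())
        if len(idx) < n:
            raise DelineationError(
                f"sample {key!r} has only {len(idx)} isolates (< {n}); "
                "lower the rarefaction depth"
            )
        keep.extend(sorted(rng.choice(idx, size=n, replace=False).tolist()))
    return table.subset(np.array(sorted(keep)))
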