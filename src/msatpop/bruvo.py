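"""Bruvo's stepwise-mutation genetic distance for microsatellites.

Under the stepwise mutation model the chance that two alleles differing by
``x`` repeat units share recent ancestry decays geometrically, giving the
per-allele distance ``d = 1 - 2**(-|x|)``.  For diploid genotypes the two
one-to-one allele assignments are enumerated and the assignment with the
smallest mean per-pair distance is taken; whole-genotype distance is the
unweighted mean over loci typed in both individuals.  Distances are always
computed in repeat units, never base pairs — the model is defined on
repeat counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeTable


class BruvoError(ValueError):
    pass


def allele_distance(a: int, b: int) -> float:
    """Bruvo distance between two alleles given as repeat counts."""
    if a == MISSING or b == MISSING:
        raise BruvoError("allele_distance requires non-missing alleles")
    return 1.0 - 2.0 ** (-abs(a - b))


def genotype_locus_distance(g1: tuple[int, int], g2: tuple[int, int]) -> float:
    """Diploid single-locus Bruvo distance (equal-ploidy rule).

    Minimum over the two one-to-one allele assignments of the mean
    per-pair allele distance; for ploidy 2 this equals a minimum-weight
    perfect matching.
    """
    a1, a2 = g1
    b1, b2 = g2
    straight = (allele_distance(a1, b1) + allele_distance(a2, b2)) / 2.0
    crossed = (allele_distance(a1, b2) + allele_distance(a2, b1)) / 2.0
    return min(straight, crossed)


def genotype_distance(g1: dict, g2: dict,
                      return_loci: bool = False):
    """Mean single-locus distance over loci non-missing in both genotypes.

    ``g1``/``g2`` map locus name to an allele pair or None (missing).
    """
    shared = [loc for loc in g1
              if loc in g2 and g1[loc] is not None and g2[loc] is not None]
    if not shared:
        raise BruvoError("no shared non-missing loci between genotypes")
    d = float(np.mean([genotype_locus_distance(g1[m], g2[m])
                       for m in shared]))
    return (d, shared) if return_loci else d


@dataclass
class DistanceMatrix:
    """Symmetric labelled pairwise-distance matrix in [0, 1]."""

    labels: list[str]
    values: np.ndarray
    loci: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise BruvoError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise BruvoError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise BruvoError("distance matrix diagonal is not zero")
        if self.values.min() < 0 or self.values.max() > 1 + 1e-12:
            raise BruvoError("distances outside [0, 1]")

    def __len__(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self), k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels,
                            columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="id")

    def to_phylip(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self)}\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab + "  " + "  ".join(f"{v:.6f}" for v in row)
                         + "\n")


def _locus_pair_distances(a: np.ndarray) -> np.ndarray:
    """All-pairs diploid Bruvo distances at one locus.

    ``a`` is (n, 2) repeat counts (MISSING allowed).  Returns (n, n) with
    NaN where either genotype is missing.
    """
    a = a.astype(float)
    a[a == MISSING] = np.nan

    def d(x, y):  # pairwise allele distance, broadcasting (n,1) vs (1,n)
        return 1.0 - 2.0 ** (-np.abs(x[:, None] - y[None, :]))

    d11 = d(a[:, 0], a[:, 0])
    d22 = d(a[:, 1], a[:, 1])
    d12 = d(a[:, 0], a[:, 1])
    d21 = d(a[:, 1], a[:, 0])
    return np.minimum((d11 + d22) / 2.0, (d12 + d21) / 2.0)


def distance_matrix(table: GenotypeTable,
                    loci: list[str] | None = None) -> DistanceMatrix:
    """All-pairs genotype distance over a table.

    ``loci`` may repeat locus names (used by the locus bootstrap); the
    mean is then over the sampled multiset.  Pairwise-incomplete loci are
    excluded from each pair's average; a pair sharing no typed locus is an
    error naming the offending pair.
    """
    if len(table) < 2:
        raise BruvoError("need at least two entities for a distance matrix")
    loci = list(loci) if loci is not None else list(table.loci)
    idx = {name: j for j, name in enumerate(table.loci)}
    n = len(table)
    total = np.zeros((n, n))
    count = np.zeros((n, n))
    for name in loci:
        dj = _locus_pair_distances(table.alleles[:, idx[name], :].copy())
        ok = ~np.isnan(dj)
        total[ok] += dj[ok]
        count += ok
    np.fill_diagonal(count, 1)  # diagonal distance is 0 regardless
    np.fill_diagonal(total, 0)
    if (count == 0).any():
        i, j = np.argwhere(count == 0)[0]
        raise BruvoError(
            f"no shared non-missing loci for pair "
            f"({table.ids[i]!r}, {table.ids[j]!r})"
        )
    vals = total / count
    vals = (vals + vals.T) / 2.0  # enforce exact symmetry
    return DistanceMatrix(list(table.ids), vals, loci)
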