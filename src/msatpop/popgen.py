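"""Allele-frequency statistics: heterozygosity, probability of identity,
and fixation indices.

Conventions follow the classic multilocus-codominant toolkit: observed
heterozygosity Ho is the fraction of heterozygous individuals, expected
heterozygosity He = 1 - sum(p_i^2), unbiased uHe = 2N/(2N-1) * He;
probability of identity PI per locus is sum(p_i^4) + sum_{i<j}
(2 p_i p_j)^2, multiplied across loci; F_ST = (Ht - Hs)/Ht and
F_IS = (Hs - mean Ho)/Hs per locus, summarized as the unweighted mean
across loci +/- SE (sd/sqrt(L)).

Frequencies are estimated from isolate-level genotypes by default; pass a
strain-representative table for strain-level estimates (the two can
differ when strains are unevenly abundant).
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeTable

logger = logging.getLogger(__name__)


class PopgenError(ValueError):
    pass


def allele_counts_per_locus(table: GenotypeTable) -> dict[str, int]:
    """Number of distinct non-missing allele values per locus."""
    out = {}
    for j, name in enumerate(table.loci):
        vals = table.alleles[:, j, :].ravel()
        out[name] = int(len(np.unique(vals[vals != MISSING])))
    return out


@dataclass
class AlleleFrequencies:
    """Per-locus allele frequencies and the diploid sample sizes behind
    them."""

    freqs: dict[str, dict[int, float]]  # locus -> allele -> frequency
    n: dict[str, int]                   # locus -> diploid individuals used

    @classmethod
    def from_table(cls, table: GenotypeTable) -> "AlleleFrequencies":
        freqs, ns = {}, {}
        for j, name in enumerate(table.loci):
            a = table.alleles[:, j, :]
            ok = a[:, 0] != MISSING
            ns[name] = int(ok.sum())
            if ns[name] == 0:
                logger.warning("locus %s: no complete genotypes; skipped",
                               name)
                continue
            vals, counts = np.unique(a[ok].ravel(), return_counts=True)
            tot = counts.sum()
            freqs[name] = {int(v): c / tot for v, c in zip(vals, counts)}
        return cls(freqs, ns)


def heterozygosity(table: GenotypeTable) -> pd.DataFrame:
    """Per-locus Ho, He and uHe.

    The returned frame also carries ``n`` (complete diploid genotypes at
    the locus).  Use :func:`heterozygosity_summary` for the across-locus
    means and the fraction of individuals with at least one heterozygous
    locus.
    """
    af = AlleleFrequencies.from_table(table)
    rows = []
    for j, name in enumerate(table.loci):
        if name not in af.freqs:
            continue
        a = table.alleles[:, j, :]
        ok = a[:, 0] != MISSING
        n = af.n[name]
        ho = float(np.mean(a[ok, 0] != a[ok, 1]))
        he = 1.0 - sum(p ** 2 for p in af.freqs[name].values())
        uhe = he * (2 * n) / (2 * n - 1) if n > 0 else np.nan
        rows.append({"locus": name, "n": n, "Ho": ho, "He": he, "uHe": uhe})
    return pd.DataFrame(rows).set_index("locus")


def heterozygosity_summary(table: GenotypeTable) -> dict:
    per_locus = heterozygosity(table)
    a = table.alleles
    typed = a[:, :, 0] != MISSING
    het = (a[:, :, 0] != a[:, :, 1]) & typed
    frac_het_individuals = float(np.mean(het.any(axis=1)))
    return {
        "Ho_mean": float(per_locus["Ho"].mean()),
        "He_mean": float(per_locus["He"].mean()),
        "uHe_mean": float(per_locus["uHe"].mean()),
        "pct_individuals_with_het_locus": 100.0 * frac_het_individuals,
    }


def probability_of_identity(freqs: AlleleFrequencies) -> tuple[pd.Series, float]:
    """Per-locus PI and the overall product across loci.

    PI is the chance two unrelated individuals drawn under random mating
    share a genotype at the locus: sum p_i^4 + sum_{i<j} (2 p_i p_j)^2.
    """
    per = {}
    for name, fr in freqs.freqs.items():
        p = np.array(list(fr.values()))
        pi = float(np.sum(p ** 4))
        pi += float(sum((2 * p[i] * p[j]) ** 2
                        for i in range(len(p)) for j in range(i + 1, len(p))))
        per[name] = pi
    series = pd.Series(per, name="PI")
    return series, float(series.prod())


def fixation_indices(table: GenotypeTable, subpop_labels) -> pd.DataFrame:
    """Per-locus F_ST and F_IS over predefined subpopulations.

    Hs is the mean subpopulation He, Ht the He of the pooled population;
    F_ST = (Ht - Hs)/Ht and F_IS = (Hs - mean subpop Ho)/Hs.  Loci with
    Ht = 0 (F_ST) or Hs = 0 (F_IS) are excluded from the respective
    summary with a log entry.
    """
    labels = np.asarray(subpop_labels)
    if len(labels) != len(table):
        raise PopgenError("subpopulation labels do not match table")
    pops = pd.unique(labels)
    if len(pops) < 2:
        raise PopgenError("F_ST requires at least two subpopulations")

    rows = []
    for j, name in enumerate(table.loci):
        a = table.alleles[:, j, :]
        ok = a[:, 0] != MISSING
        if not ok.any():
            continue
        hs_vals, ho_vals = [], []
        for pop in pops:
            m = ok & (labels == pop)
            if not m.any():
                continue
            vals, counts = np.unique(a[m].ravel(), return_counts=True)
            p = counts / counts.sum()
            hs_vals.append(1.0 - np.sum(p ** 2))
            ho_vals.append(float(np.mean(a[m, 0] != a[m, 1])))
        vals, counts = np.unique(a[ok].ravel(), return_counts=True)
        p = counts / counts.sum()
        ht = 1.0 - float(np.sum(p ** 2))
        hs = float(np.mean(hs_vals))
        ho = float(np.mean(ho_vals))
        fst = (ht - hs) / ht if ht > 0 else np.nan
        fis = (hs - ho) / hs if hs > 0 else np.nan
        if ht == 0:
            logger.info("locus %s: Ht=0, excluded from F_ST mean", name)
        if hs == 0:
            logger.info("locus %s: Hs=0, excluded from F_IS mean", name)
        rows.append({"locus": name, "Hs": hs, "Ht": ht, "Ho_mean": ho,
                     "F_ST": fst, "F_IS": fis})
    return pd.DataFrame(rows).set_index("locus")


def fixation_summary(per_locus: pd.DataFrame) -> dict:
    """Unweighted mean +/- SE (sd/sqrt(L)) across retained loci."""
    out = {}
    for stat in ("F_ST", "F_IS"):
        v = per_locus[stat].dropna().to_numpy()
        out[stat] = float(np.mean(v))
        out[f"{stat}_se"] = float(np.std(v, ddof=1) / np.sqrt(len(v))) \
            if len(v) > 1 else float("nan")
        out[f"{stat}_n_loci"] = int(len(v))
    return out
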