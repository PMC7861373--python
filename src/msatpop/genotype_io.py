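"""Reading, validating and writing microsatellite genotype tables.

Fragment-analysis software exports allele calls as fragment sizes in base
pairs.  All downstream genetics here (Bruvo distance, F-statistics, the
admixture sampler) operates on repeat counts, so conversion happens at the
I/O boundary: ``repeats = round((size - offset) / repeat_len)`` with
round-half-away-from-zero, where ``offset`` is the non-repeat flanking
length of the amplicon and ``repeat_len`` the repeat-unit length in bp.

Missing data is encoded in files as an empty cell or ``NA`` — never 0,
because 0 is a legal repeat difference.  Internally a missing locus is the
sentinel value -1 in both allele slots.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

MISSING = -1

#: metadata columns of an isolate table, in file order
ISOLATE_META = ["isolate_id", "vintage", "vineyard", "barrel", "stage"]
STAGES = ("early", "mid", "late")

#: the locus panel used for S. uvarum strain typing
DEFAULT_LOCI = ("L1", "L2", "L3", "L4", "L7", "L8", "L9",
                "NB1", "NB4", "NB8", "NB9")


class GenotypeIOError(ValueError):
    """Raised for malformed genotype or locus-configuration input."""


@dataclass(frozen=True)
class Locus:
    """Conversion parameters for one microsatellite locus."""

    name: str
    repeat_len: int  # bp per repeat unit, >= 1
    offset: int = 0  # non-repeat flanking bp subtracted before conversion

    def __post_init__(self) -> None:
        if self.repeat_len < 1:
            raise GenotypeIOError(
                f"locus {self.name!r}: repeat_len must be >= 1, "
                f"got {self.repeat_len}"
            )

    def size_to_repeats(self, size: float) -> int:
        """Convert a fragment size in bp to a repeat count.

        Rounds half away from zero and logs when the remainder exceeds
        0.2 repeat units (a possible off-ladder allele, given that
        fragment sizing carries roughly +/-1 bp of noise).
        """
        x = (size - self.offset) / self.repeat_len
        r = int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)
        if abs(x - r) > 0.2:
            logger.warning(
                "locus %s: size %.1f is %.2f repeat units off the ladder",
                self.name, size, abs(x - r),
            )
        if r < 0:
            raise GenotypeIOError(
                f"locus {self.name!r}: size {size} converts to a negative "
                f"repeat count ({r}); check offset/repeat_len"
            )
        return r

    def repeats_to_size(self, repeats: int) -> int:
        return repeats * self.repeat_len + self.offset


class LocusConfig:
    """An ordered collection of :class:`Locus` entries, one per locus."""

    def __init__(self, loci: list[Locus]):
        names = [l.name for l in loci]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise GenotypeIOError(f"duplicate locus name(s): {sorted(dupes)}")
        self._loci = {l.name: l for l in loci}

    @property
    def names(self) -> list[str]:
        return list(self._loci)

    def __len__(self) -> int:
        return len(self._loci)

    def __getitem__(self, name: str) -> Locus:
        return self._loci[name]

    def __iter__(self):
        return iter(self._loci.values())

    def __eq__(self, other) -> bool:
        return isinstance(other, LocusConfig) and self._loci == other._loci

    @classmethod
    def default(cls, names=DEFAULT_LOCI, repeat_len: int = 3,
                offset: int = 0) -> "LocusConfig":
        """Synthetic-work default: trinucleotide repeats, zero offset.

        Real-data runs must supply the true per-locus motifs and offsets
        from the primer literature; guessing them silently would corrupt
        every downstream distance.
        """
        return cls([Locus(n, repeat_len, offset) for n in names])


def read_locus_config(path) -> LocusConfig:
    """Read a YAML locus configuration.

    Expected layout::

        loci:
          L1: {repeat_len: 3, offset: 100}
          L2: {repeat_len: 3, offset: 0}
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "loci" not in raw:
        raise GenotypeIOError(f"{path}: expected a top-level 'loci' mapping")
    loci = []
    for name, entry in raw["loci"].items():
        if not isinstance(entry, dict) or "repeat_len" not in entry:
            raise GenotypeIOError(
                f"{path}: locus {name!r} is missing repeat_len "
                "(conversion impossible)"
            )
        loci.append(Locus(str(name), int(entry["repeat_len"]),
                          int(entry.get("offset", 0))))
    return LocusConfig(loci)


def write_locus_config(config: LocusConfig, path) -> None:
    data = {"loci": {l.name: {"repeat_len": l.repeat_len, "offset": l.offset}
                     for l in config}}
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class GenotypeTable:
    """Diploid multilocus genotypes with per-entity metadata.

    ``alleles`` has shape (n, n_loci, 2), dtype int, canonically ordered
    (A1 <= A2) within each locus, with both slots set to :data:`MISSING`
    for loci that failed to amplify.
    """

    ids: list[str]
    loci: list[str]
    alleles: np.ndarray
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        if self.alleles.shape != (len(self.ids), len(self.loci), 2):
            raise GenotypeIOError(
                f"allele array shape {self.alleles.shape} does not match "
                f"{len(self.ids)} ids x {len(self.loci)} loci x 2"
            )
        if len(set(self.ids)) != len(self.ids):
            raise GenotypeIOError("entity ids are not unique")
        # canonical order and consistent missing flags
        self.alleles = np.sort(self.alleles, axis=2)
        half = (self.alleles == MISSING).any(axis=2)
        self.alleles[half] = MISSING
        if len(self.metadata) and len(self.metadata) != len(self.ids):
            raise GenotypeIOError("metadata length does not match ids")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (n, n_loci): True where the locus is missing."""
        return self.alleles[:, :, 0] == MISSING

    def subset(self, indices) -> "GenotypeTable":
        indices = np.asarray(indices, dtype=np.int64)
        meta = (self.metadata.iloc[indices].reset_index(drop=True)
                if len(self.metadata) else pd.DataFrame())
        return GenotypeTable([self.ids[i] for i in indices], list(self.loci),
                             self.alleles[indices].copy(), meta)

    def genotype(self, i: int) -> dict[str, tuple[int, int] | None]:
        """Genotype of entity *i* as {locus: (A1, A2) or None}."""
        out = {}
        for j, loc in enumerate(self.loci):
            a = self.alleles[i, j]
            out[loc] = None if a[0] == MISSING else (int(a[0]), int(a[1]))
        return out


def _parse_allele(cell) -> float | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    s = str(cell).strip()
    if s == "" or s.upper() == "NA":
        return None
    try:
        v = float(s)
    except ValueError:
        return None
    if v == 0:
        raise GenotypeIOError(
            "allele size 0 found: missing data must be an empty cell or "
            "'NA', never numeric 0"
        )
    return v


def _read_genotype_frame(df: pd.DataFrame, config: LocusConfig,
                         meta_cols: list[str], id_col: str,
                         sizes: bool) -> GenotypeTable:
    allele_cols = [c for c in df.columns if c not in meta_cols]
    expected = [f"{l}_{a}" for l in config.names for a in ("A1", "A2")]
    unknown = sorted(set(allele_cols) - set(expected))
    if unknown:
        raise GenotypeIOError(f"unknown locus column(s): {unknown}")
    absent = sorted(set(expected) - set(allele_cols))
    if absent:
        raise GenotypeIOError(f"missing allele column(s): {absent}")

    n, L = len(df), len(config)
    alleles = np.full((n, L, 2), MISSING, dtype=np.int64)
    for j, locus in enumerate(config):
        for k, slot in enumerate(("A1", "A2")):
            col = df[f"{locus.name}_{slot}"]
            for i, cell in enumerate(col):
                v = _parse_allele(cell)
                if v is None:
                    continue
                alleles[i, j, k] = (locus.size_to_repeats(v) if sizes
                                    else int(round(v)))
    # either allele unparseable -> whole locus missing
    half = (alleles == MISSING).any(axis=2)
    alleles[half] = MISSING

    all_missing = half.all(axis=1)
    if all_missing.any():
        dropped = df.loc[all_missing, id_col].tolist()
        logger.warning(
            "dropping %d row(s) with no amplified locus "
            "(presumed non-target or failed isolates): %s",
            len(dropped), dropped,
        )
        keep = ~all_missing
        df = df.loc[keep].reset_index(drop=True)
        alleles = alleles[keep]

    ids = df[id_col].astype(str).tolist()
    meta = df[meta_cols].astype(str).reset_index(drop=True)
    return GenotypeTable(ids, config.names, alleles, meta)


def read_isolates(path, config: LocusConfig) -> GenotypeTable:
    """Read an isolate genotype table (CSV, fragment sizes in bp).

    Columns: ``isolate_id, vintage, vineyard, barrel, stage`` plus
    ``<locus>_A1, <locus>_A2`` for every configured locus.  Rows where no
    locus amplified are dropped with a warning; partially amplified loci
    are flagged missing and the row is retained (exclusion of repeated
    partial amplifiers is a pipeline policy, applied at delineation).
    """
    df = pd.read_csv(path, dtype=str)
    for col in ISOLATE_META:
        if col not in df.columns:
            raise GenotypeIOError(f"{path}: missing metadata column {col!r}")
    table = _read_genotype_frame(df, config, ISOLATE_META, "isolate_id",
                                 sizes=True)
    bad = set(table.metadata["stage"]) - set(STAGES)
    if bad:
        raise GenotypeIOError(f"unknown fermentation stage(s): {sorted(bad)}")
    return table


def write_isolates(table: GenotypeTable, config: LocusConfig, path) -> None:
    """Write an isolate table back to CSV in fragment-size units."""
    _write_genotype_frame(table, config, path, sizes=True)


def read_reference_strains(path, config: LocusConfig,
                           sizes: bool = True) -> GenotypeTable:
    """Read a reference strain MLG table (CSV).

    Columns: ``strain_name, origin`` plus ``<locus>_A1, <locus>_A2``.
    ``sizes=False`` reads allele columns as repeat counts directly.
    """
    df = pd.read_csv(path, dtype=str)
    for col in ("strain_name", "origin"):
        if col not in df.columns:
            raise GenotypeIOError(f"{path}: missing column {col!r}")
    return _read_genotype_frame(df, config, ["strain_name", "origin"],
                                "strain_name", sizes=sizes)


def _write_genotype_frame(table: GenotypeTable, config: LocusConfig | None,
                          path, sizes: bool) -> None:
    cols = {}
    if len(table.metadata):
        for c in table.metadata.columns:
            cols[c] = table.metadata[c].tolist()
    else:
        cols["strain_name"] = table.ids
    for j, name in enumerate(table.loci):
        for k, slot in enumerate(("A1", "A2")):
            vals = []
            for i in range(len(table)):
                a = table.alleles[i, j, k]
                if a == MISSING:
                    vals.append("")
                elif sizes:
                    vals.append(str(config[name].repeats_to_size(int(a))))
                else:
                    vals.append(str(int(a)))
            cols[f"{name}_{slot}"] = vals
    pd.DataFrame(cols).to_csv(path, index=False)


def write_strain_table(table: GenotypeTable, path,
                       config: LocusConfig | None = None) -> None:
    """Write representative strain MLGs, one row per strain.

    With a ``config`` the A1/A2 columns are fragment sizes in bp (the
    supplementary-table convention); without, raw repeat counts.
    """
    _write_genotype_frame(table, config, path, sizes=config is not None)
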