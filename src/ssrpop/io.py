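"""Readers and writers for genotype, trait and metadata tables.

Genotype files follow the GenAlEx convention: one header row, an accession-id
column, then two columns per SSR locus holding allele fragment sizes in base
pairs, with ``0`` (configurable) marking a missing allele.  Trait files carry
the 12 integer-coded spike/grain descriptors.  A STRUCTURE-compatible
two-rows-per-individual export is provided for the admixture sampler.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: internal sentinel for a missing allele copy (never a valid fragment size)
MISSING = -1

#: the five collection regions and their climate stages
REGION_CLIMATE = {
    "Sousse": "LSA",
    "Mahdia": "LSA",
    "Kairouan": "HA",
    "Gabes": "MA",
    "Medenine": "MA",
}

#: canonical trait order for the 12 spike- and grain-related descriptors
TRAIT_ORDER = (
    "SS", "SL", "AL", "SC", "NS", "GlC",
    "GN", "GSp", "GSz", "GC", "AC", "SD",
)


@dataclass(frozen=True)
class LocusInfo:
    """Metadata for one SSR marker."""

    name: str
    chromosome: str = ""
    repeat_unit: int = 2
    size_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.repeat_unit < 1:
            raise ValueError(f"repeat_unit must be >= 1, got {self.repeat_unit}")


@dataclass(frozen=True)
class TraitDescriptor:
    """One coded morphological descriptor with its permitted class codes."""

    name: str
    universe: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.universe) == 0:
            raise ValueError(f"trait {self.name}: empty class universe")


#: default IPGRI/UPOV-style class universes for the 12 descriptors
DEFAULT_TRAITS: tuple[TraitDescriptor, ...] = (
    TraitDescriptor("SS", (1, 2, 3, 4, 5)),
    TraitDescriptor("SL", (1, 3, 5, 7, 9)),
    TraitDescriptor("AL", (1, 3, 5, 7, 9)),
    TraitDescriptor("SC", (1, 2, 3, 4, 5)),
    TraitDescriptor("NS", (1, 3, 5, 7, 9)),
    TraitDescriptor("GlC", (1, 2, 3, 4, 5)),
    TraitDescriptor("GN", (1, 3, 5, 7, 9)),
    TraitDescriptor("GSp", (1, 2, 3, 4, 5)),
    TraitDescriptor("GSz", (1, 3, 5, 7, 9)),
    TraitDescriptor("GC", (1, 2, 3, 4, 5)),
    TraitDescriptor("AC", (1, 2, 3, 4, 5)),
    TraitDescriptor("SD", (1, 3, 5, 7, 9)),
)


class GenotypeMatrix:
    """N accessions x L loci x 2 allele copies, sizes in base pairs.

    ``calls`` is an int array of shape (N, L, 2) with :data:`MISSING` (-1)
    for absent allele copies.  A call is always both-present or both-missing.
    """

    def __init__(
        self,
        accession_ids: Sequence[str],
        loci: Sequence[LocusInfo],
        calls: np.ndarray,
    ) -> None:
        ids = list(accession_ids)
        if len(set(ids)) != len(ids):
            dupes = sorted({a for a in ids if ids.count(a) > 1})
            raise ValueError(f"duplicate accession ids: {dupes}")
        names = [loc.name for loc in loci]
        if len(set(names)) != len(names):
            raise ValueError("duplicate locus names")
        calls = np.asarray(calls, dtype=np.int64)
        if calls.shape != (len(ids), len(loci), 2):
            raise ValueError(
                f"calls shape {calls.shape} != ({len(ids)}, {len(loci)}, 2)"
            )
        half = (calls == MISSING).sum(axis=2) == 1
        if half.any():
            raise ValueError("half-calls present; coerce to missing first")
        if ((calls != MISSING) & (calls <= 0)).any():
            raise ValueError("allele sizes must be positive integers")
        self.accession_ids = ids
        self.loci = list(loci)
        self.calls = calls

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_names(self) -> list[str]:
        return [loc.name for loc in self.loci]

    def missing_mask(self) -> np.ndarray:
        """Boolean (N, L): True where the call is missing."""
        return self.calls[:, :, 0] == MISSING

    def missing_fraction(self) -> pd.Series:
        """Per-locus missing fraction count(MISSING)/N."""
        frac = self.missing_mask().mean(axis=0)
        return pd.Series(frac, index=self.locus_names, name="missing_fraction")

    def subset(self, accessions: Sequence[str] | np.ndarray) -> "GenotypeMatrix":
        """Row-subset by accession id or boolean/integer index."""
        idx = _as_row_index(accessions, self.accession_ids)
        return GenotypeMatrix(
            [self.accession_ids[i] for i in idx], self.loci, self.calls[idx]
        )

    def subset_loci(self, locus_idx: Sequence[int]) -> "GenotypeMatrix":
        locus_idx = list(locus_idx)
        return GenotypeMatrix(
            self.accession_ids,
            [self.loci[j] for j in locus_idx],
            self.calls[:, locus_idx, :],
        )

    def drop_all_missing(self) -> "GenotypeMatrix":
        """Drop accessions missing at every locus (warn with their ids)."""
        all_missing = self.missing_mask().all(axis=1)
        if all_missing.any():
            dropped = [a for a, m in zip(self.accession_ids, all_missing) if m]
            warnings.warn(
                f"dropped {len(dropped)} accession(s) with all loci missing: "
                f"{dropped}",
                stacklevel=2,
            )
            return self.subset(~all_missing)
        return self

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.accession_ids == other.accession_ids
            and self.locus_names == other.locus_names
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:
        return (
            f"GenotypeMatrix(N={self.n_accessions}, L={self.n_loci}, "
            f"missing={self.missing_mask().mean():.3f})"
        )


class TraitMatrix:
    """N accessions x 12 integer phenotypic class codes."""

    def __init__(
        self,
        accession_ids: Sequence[str],
        codes: np.ndarray,
        traits: Sequence[TraitDescriptor] = DEFAULT_TRAITS,
    ) -> None:
        ids = list(accession_ids)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate accession ids")
        traits = tuple(traits)
        codes = np.asarray(codes, dtype=np.int64)
        if codes.shape != (len(ids), len(traits)):
            raise ValueError(
                f"codes shape {codes.shape} != ({len(ids)}, {len(traits)})"
            )
        for j, tr in enumerate(traits):
            bad = ~np.isin(codes[:, j], tr.universe)
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"accession {ids[i]!r}, trait {tr.name}: code "
                    f"{codes[i, j]} outside universe {tr.universe}"
                )
        self.accession_ids = ids
        self.traits = traits
        self.codes = codes

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def trait_names(self) -> list[str]:
        return [t.name for t in self.traits]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.codes, index=self.accession_ids, columns=self.trait_names
        )

    def subset(self, accessions: Sequence[str] | np.ndarray) -> "TraitMatrix":
        idx = _as_row_index(accessions, self.accession_ids)
        return TraitMatrix(
            [self.accession_ids[i] for i in idx], self.codes[idx], self.traits
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TraitMatrix):
            return NotImplemented
        return (
            self.accession_ids == other.accession_ids
            and self.traits == other.traits
            and np.array_equal(self.codes, other.codes)
        )


@dataclass
class AccessionMetadata:
    """Collection metadata for one accession."""

    accession_id: str
    landrace: str | None = None
    region: str | None = None
    climate: str | None = None
    lat: float | None = None
    lon: float | None = None

    def __post_init__(self) -> None:
        if self.region in REGION_CLIMATE and self.climate is not None:
            expected = REGION_CLIMATE[self.region]
            if self.climate != expected:
                raise ValueError(
                    f"{self.accession_id}: region {self.region} implies "
                    f"climate {expected}, got {self.climate}"
                )


def _as_row_index(sel, ids: list[str]) -> list[int]:
    arr = np.asarray(sel)
    if arr.dtype == bool:
        return list(np.flatnonzero(arr))
    if np.issubdtype(arr.dtype, np.integer):
        return [int(i) for i in arr]
    pos = {a: i for i, a in enumerate(ids)}
    return [pos[a] for a in sel]


# ---------------------------------------------------------------------------
# delimited-text readers / writers


def _sniff_rows(path) -> list[list[str]]:
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = "\t" if "\t" in sample.splitlines()[0] else ","
        return [row for row in csv.reader(fh, delimiter=delim) if row]


def read_genotypes(
    path,
    locus_info: Sequence[LocusInfo],
    missing_code: int = 0,
    drop_all_missing: bool = False,
) -> GenotypeMatrix:
    """Read a two-columns-per-locus genotype table.

    Half-calls (one allele present, one missing) are coerced to fully
    missing; the number of coercions is logged.  With *drop_all_missing*,
    accessions missing at every locus are removed with a warning (the
    analysis-time policy); by default the parsed table is returned as-is.
    """
    rows = _sniff_rows(path)
    header, body = rows[0], rows[1:]
    expected = [loc.name for loc in locus_info for _ in range(2)]
    got = [h.strip() for h in header[1:]]
    if got != expected:
        unknown = [h for h in got if h not in {loc.name for loc in locus_info}]
        raise ValueError(
            f"genotype header mismatch: unknown/extra locus columns {unknown or got}; "
            f"expected {expected}"
        )
    ids: list[str] = []
    calls = np.empty((len(body), len(locus_info), 2), dtype=np.int64)
    for i, row in enumerate(body):
        ids.append(row[0].strip())
        for j in range(len(locus_info)):
            for c in range(2):
                cell = row[1 + 2 * j + c].strip()
                try:
                    val = int(cell)
                except ValueError:
                    raise ValueError(
                        f"non-integer allele size {cell!r} for accession "
                        f"{row[0]!r}, locus {locus_info[j].name}"
                    ) from None
                calls[i, j, c] = MISSING if val == missing_code else val
    half = (calls == MISSING).sum(axis=2) == 1
    n_half = int(half.sum())
    if n_half:
        logger.warning("coerced %d half-call(s) to missing", n_half)
        calls[half] = MISSING
    g = GenotypeMatrix(ids, locus_info, calls)
    return g.drop_all_missing() if drop_all_missing else g


def write_genotypes(g: GenotypeMatrix, path, missing_code: int = 0) -> None:
    """Write the two-columns-per-locus genotype table (CSV)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["accession"] + [n for n in g.locus_names for _ in range(2)])
        out = np.where(g.calls == MISSING, missing_code, g.calls)
        for i, acc in enumerate(g.accession_ids):
            w.writerow([acc] + out[i].ravel().tolist())


def allele_code_maps(g: GenotypeMatrix) -> list[dict[int, int]]:
    """Per-locus dictionary mapping allele size -> 1-based integer code."""
    maps = []
    for j in range(g.n_loci):
        sizes = np.unique(g.calls[:, j, :])
        sizes = sizes[sizes != MISSING]
        maps.append({int(s): k + 1 for k, s in enumerate(sizes)})
    return maps


def write_structure_format(g: GenotypeMatrix, path=None) -> str:
    """Export genotypes as two rows per accession with -9 for missing.

    Allele sizes are recoded to per-locus 1-based integer codes (see
    :func:`allele_code_maps`).  Returns the text; writes it if *path* given.
    """
    maps = allele_code_maps(g)
    lines = []
    for i, acc in enumerate(g.accession_ids):
        for c in range(2):
            cells = [acc]
            for j in range(g.n_loci):
                a = g.calls[i, j, c]
                cells.append("-9" if a == MISSING else str(maps[j][int(a)]))
            lines.append("\t".join(cells))
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_traits(
    path, descriptor_table: Sequence[TraitDescriptor] = DEFAULT_TRAITS
) -> TraitMatrix:
    """Read the 12-column coded trait table; all traits are required."""
    rows = _sniff_rows(path)
    header, body = rows[0], rows[1:]
    names = [h.strip() for h in header[1:]]
    expected = [t.name for t in descriptor_table]
    if names != expected:
        raise ValueError(f"trait header {names} != required {expected}")
    ids = [row[0].strip() for row in body]
    try:
        codes = np.array(
            [[int(cell) for cell in row[1:]] for row in body], dtype=np.int64
        )
    except ValueError as exc:
        raise ValueError(f"non-integer trait code: {exc}") from None
    if codes.shape[1] != len(descriptor_table):
        raise ValueError(
            f"expected {len(descriptor_table)} trait columns, got {codes.shape[1]}"
        )
    return TraitMatrix(ids, codes, descriptor_table)


def write_traits(t: TraitMatrix, path) -> None:
    t.to_frame().rename_axis("accession").to_csv(path)


def read_metadata(path) -> list[AccessionMetadata]:
    """Read accession metadata (id, landrace, region, climate, lat, lon)."""
    df = pd.read_csv(path, sep=None, engine="python")
    out = []
    for _, row in df.iterrows():
        def _opt(key):
            v = row.get(key)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) or v == "" else v
        lat, lon = _opt("lat"), _opt("lon")
        out.append(
            AccessionMetadata(
                accession_id=str(row["accession"]),
                landrace=_opt("landrace"),
                region=_opt("region"),
                climate=_opt("climate"),
                lat=None if lat is None else float(lat),
                lon=None if lon is None else float(lon),
            )
        )
    return out


def write_metadata(meta: Iterable[AccessionMetadata], path) -> None:
    rows = [
        {
            "accession": m.accession_id,
            "landrace": m.landrace,
            "region": m.region,
            "climate": m.climate,
            "lat": m.lat,
            "lon": m.lon,
        }
        for m in meta
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def metadata_frame(meta: Iterable[AccessionMetadata]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "accession": m.accession_id,
                "landrace": m.landrace,
                "region": m.region,
                "climate": m.climate,
                "lat": m.lat,
                "lon": m.lon,
            }
            for m in meta
        ]
    )
    return df.set_index("accession")
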