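"""Genetic, morphological and geographic distances, MSN and Mantel tests.

Implements Nei's (1972) standard genetic distance between strata, Bruvo's
stepwise-mutation distance between diploid SSR genotypes, the codominant
genotypic squared distance used for AMOVA, minimum spanning networks (MST
plus co-minimal tie edges), Euclidean trait distance, haversine geographic
distance with the ln(1 + d) transform, and a permutation Mantel test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, LocusInfo, TraitMatrix

EARTH_RADIUS_KM = 6371.0088
MSN_TIE_TOL = 1e-12


@dataclass
class DistanceMatrix:
    """Symmetric labelled distance matrix with a kind tag."""

    labels: list[str]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        finite = np.isfinite(v)
        if not np.allclose(v[finite], v.T[finite.T], atol=1e-12):
            raise ValueError("matrix not symmetric")
        if not (np.diag(v) == 0).all():
            raise ValueError("diagonal must be exactly 0")
        if (v[finite] < 0).any():
            raise ValueError("distances must be non-negative")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(
            list(labels), self.values[np.ix_(idx, idx)], self.kind
        )


# ---------------------------------------------------------------------------
# Nei (1972) standard distance between strata


def nei_distance(
    freqs_a: Mapping[str, Mapping[int, float]],
    freqs_b: Mapping[str, Mapping[int, float]],
    per_locus_average: bool = False,
) -> float:
    """Nei's standard distance D = -ln(Jxy / sqrt(Jx Jy)).

    *freqs_a*/*freqs_b* map locus -> {allele: frequency}.  By default the
    J sums are pooled across loci before the ratio (Nei 1972); the
    per-locus-averaged identity is available behind a flag.  Disjoint
    supports at all loci give infinity (flagged by a warning).
    """
    loci = [l for l in freqs_a if freqs_a[l] and freqs_b.get(l)]
    if not loci:
        raise ValueError("no shared loci with frequencies")
    jxy = jx = jy = 0.0
    identities = []
    for loc in loci:
        pa, pb = freqs_a[loc], freqs_b[loc]
        support = set(pa) | set(pb)
        x = np.array([pa.get(a, 0.0) for a in sorted(support)])
        y = np.array([pb.get(a, 0.0) for a in sorted(support)])
        jxy += float(x @ y)
        jx += float(x @ x)
        jy += float(y @ y)
        identities.append(float(x @ y) / np.sqrt(float(x @ x) * float(y @ y)))
    if per_locus_average:
        identity = float(np.mean(identities))
    else:
        identity = jxy / np.sqrt(jx * jy)
    if identity == 0.0:
        warnings.warn("zero genetic identity: distance infinite", stacklevel=2)
        return np.inf
    return float(-np.log(identity))


def nei_matrix(
    g: GenotypeMatrix, strata: Mapping[str, Sequence[str]], **kw
) -> DistanceMatrix:
    """Pairwise Nei distances between strata."""
    from .markers import allele_frequencies

    table = allele_frequencies(g, strata)
    labels = list(strata)
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d[i, j] = d[j, i] = nei_distance(table[labels[i]], table[labels[j]], **kw)
    return DistanceMatrix(labels, d, "nei")


# ---------------------------------------------------------------------------
# Bruvo distance


def _bruvo_locus(a: np.ndarray, b: np.ndarray, repeat: int) -> float:
    """Diploid per-locus Bruvo distance: minimum over the two perfect
    matchings of the mean pairwise 1 - 2^-|repeat difference|."""
    x = a / repeat
    y = b / repeat
    m = 1.0 - 2.0 ** (-np.abs(x[:, None] - y[None, :]))
    straight = (m[0, 0] + m[1, 1]) / 2.0
    crossed = (m[0, 1] + m[1, 0]) / 2.0
    return float(min(straight, crossed))


def bruvo_distance(
    genotype_a: np.ndarray,
    genotype_b: np.ndarray,
    loci: Sequence[LocusInfo],
) -> float:
    """Bruvo distance in [0, 1] between two diploid genotypes (L, 2 arrays).

    Loci missing in either genotype are dropped and the remainder averaged;
    no comparable loci raises."""
    a = np.asarray(genotype_a)
    b = np.asarray(genotype_b)
    vals = []
    for j, loc in enumerate(loci):
        if a[j, 0] == MISSING or b[j, 0] == MISSING:
            continue
        vals.append(_bruvo_locus(a[j].astype(float), b[j].astype(float), loc.repeat_unit))
    if not vals:
        raise ValueError("no comparable loci between genotypes")
    return float(np.mean(vals))


def bruvo_matrix(g: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise Bruvo distances between all accessions (vectorised)."""
    n, L = g.n_accessions, g.n_loci
    acc = np.zeros((n, n))
    cnt = np.zeros((n, n))
    for j, loc in enumerate(g.loci):
        cj = g.calls[:, j, :].astype(float) / loc.repeat_unit
        present = g.calls[:, j, 0] != MISSING
        m = np.zeros((n, n, 2, 2))
        for c1 in range(2):
            for c2 in range(2):
                m[:, :, c1, c2] = 1.0 - 2.0 ** (
                    -np.abs(cj[:, None, c1] - cj[None, :, c2])
                )
        straight = (m[:, :, 0, 0] + m[:, :, 1, 1]) / 2.0
        crossed = (m[:, :, 0, 1] + m[:, :, 1, 0]) / 2.0
        dj = np.minimum(straight, crossed)
        ok = present[:, None] & present[None, :]
        acc[ok] += dj[ok]
        cnt[ok] += 1.0
    with np.errstate(invalid="ignore"):
        d = acc / cnt
    d[cnt == 0] = np.nan
    np.fill_diagonal(d, 0.0)
    if np.isnan(d).any():
        raise ValueError("accession pairs with no comparable loci")
    d = (d + d.T) / 2.0
    return DistanceMatrix(list(g.accession_ids), d, "bruvo")


# ---------------------------------------------------------------------------
# codominant genotypic squared distance


def genotypic_squared_distance(
    genotype_a: np.ndarray, genotype_b: np.ndarray
) -> float:
    """Squared genotypic distance: per locus half the squared Euclidean
    distance between allele-count vectors, summed over comparable loci and
    rescaled by L / (comparable loci)."""
    a = np.asarray(genotype_a)
    b = np.asarray(genotype_b)
    L = a.shape[0]
    total = 0.0
    comparable = 0
    for j in range(L):
        if a[j, 0] == MISSING or b[j, 0] == MISSING:
            continue
        comparable += 1
        alleles = set(a[j].tolist()) | set(b[j].tolist())
        d2 = 0.0
        for al in alleles:
            ca = int((a[j] == al).sum())
            cb = int((b[j] == al).sum())
            d2 += (ca - cb) ** 2
        total += d2 / 2.0
    if comparable == 0:
        return 0.0
    return total * L / comparable


def genotypic_sq_matrix(g: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise squared genotypic distances (vectorised over loci)."""
    n, L = g.n_accessions, g.n_loci
    total = np.zeros((n, n))
    cnt = np.zeros((n, n))
    for j in range(L):
        cj = g.calls[:, j, :]
        present = cj[:, 0] != MISSING
        alleles = np.unique(cj[present])
        counts = np.zeros((n, alleles.size))
        for k, al in enumerate(alleles):
            counts[:, k] = (cj == al).sum(axis=1)
        gram = counts @ counts.T
        sq = np.diag(gram)[:, None] + np.diag(gram)[None, :] - 2 * gram
        ok = present[:, None] & present[None, :]
        total[ok] += sq[ok] / 2.0
        cnt[ok] += 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        d = total * L / cnt
    d[cnt == 0] = 0.0
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(list(g.accession_ids), d, "genotypic_sq")


# ---------------------------------------------------------------------------
# minimum spanning network


def minimum_spanning_network(d: DistanceMatrix) -> nx.Graph:
    """MST (Kruskal) plus every non-tree edge whose weight ties, within
    1e-12, the maximum-weight edge on the tree path between its endpoints.

    Edges carry ``weight`` and ``in_mst``/``tie`` flags.  Infinite entries
    disconnect the graph; per-component networks are returned in one graph.
    """
    full = nx.Graph()
    full.add_nodes_from(d.labels)
    for i, j in combinations(range(d.n), 2):
        w = d.values[i, j]
        if np.isfinite(w):
            full.add_edge(d.labels[i], d.labels[j], weight=float(w))
    mst = nx.minimum_spanning_tree(full, algorithm="kruskal")
    msn = nx.Graph()
    msn.add_nodes_from(d.labels)
    for u, v, data in mst.edges(data=True):
        msn.add_edge(u, v, weight=data["weight"], in_mst=True, tie=False)
    for u, v, data in full.edges(data=True):
        if msn.has_edge(u, v):
            continue
        try:
            path = nx.shortest_path(mst, u, v)
        except nx.NetworkXNoPath:
            continue
        path_max = max(
            mst[a][b]["weight"] for a, b in zip(path[:-1], path[1:])
        )
        if abs(data["weight"] - path_max) <= MSN_TIE_TOL:
            msn.add_edge(u, v, weight=data["weight"], in_mst=False, tie=True)
    return msn


def msn_tables(
    msn: nx.Graph, node_attrs: Mapping[str, Mapping] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Edge list (source, target, weight, in_mst, tie) and node table."""
    edges = pd.DataFrame(
        [
            {
                "source": u,
                "target": v,
                "weight": data["weight"],
                "in_mst": data["in_mst"],
                "tie": data["tie"],
            }
            for u, v, data in msn.edges(data=True)
        ]
    )
    rows = []
    for node in msn.nodes:
        row = {"node": node}
        if node_attrs and node in node_attrs:
            row.update(node_attrs[node])
        rows.append(row)
    return edges, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trait and geographic distances


def trait_distance(traits: TraitMatrix) -> DistanceMatrix:
    """Euclidean distance between accessions on the 12 integer codes."""
    X = traits.codes.astype(float)
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    return DistanceMatrix(list(traits.accession_ids), np.sqrt(sq), "trait")


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km between two (lat, lon) points."""
    la1, lo1, la2, lo2 = map(np.radians, (lat1, lon1, lat2, lon2))
    h = (
        np.sin((la2 - la1) / 2) ** 2
        + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2) ** 2
    )
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


def geographic_distance(
    metadata, log_transform: bool = True
) -> DistanceMatrix:
    """ln(1 + haversine km) distance between geolocated accessions.

    Accessions without coordinates are excluded (logged via warning)."""
    geo = [m for m in metadata if m.lat is not None and m.lon is not None]
    skipped = len(list(metadata)) - len(geo)
    if skipped:
        warnings.warn(
            f"excluded {skipped} accession(s) without coordinates", stacklevel=2
        )
    if len(geo) < 2:
        raise ValueError("need >= 2 geolocated accessions")
    labels = [m.accession_id for m in geo]
    lat = np.radians([m.lat for m in geo])
    lon = np.radians([m.lon for m in geo])
    h = (
        np.sin((lat[None, :] - lat[:, None]) / 2) ** 2
        + np.cos(lat[:, None])
        * np.cos(lat[None, :])
        * np.sin((lon[None, :] - lon[:, None]) / 2) ** 2
    )
    km = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    np.fill_diagonal(km, 0.0)
    km = (km + km.T) / 2.0
    d = np.log1p(km) if log_transform else km
    return DistanceMatrix(labels, d, "geographic")


# ---------------------------------------------------------------------------
# Mantel test


def mantel_test(
    da: DistanceMatrix,
    db: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """One-sided Mantel test of positive matrix association.

    r is the Pearson correlation of the lower-triangle entries; the p-value
    counts simultaneous row/column permutations of the second matrix with
    r >= observed, with the +1 correction.
    """
    if da.labels != db.labels:
        db = db.reorder(da.labels)
    x = da.condensed()
    n = da.n
    if np.std(x) == 0 or np.std(db.condensed()) == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")
    xc = x - x.mean()
    xnorm = np.sqrt((xc**2).sum())
    iu = np.triu_indices(n, k=1)

    def _r(mat: np.ndarray) -> float:
        y = mat[iu]
        yc = y - y.mean()
        return float((xc @ yc) / (xnorm * np.sqrt((yc**2).sum())))

    r_obs = _r(db.values)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _r(db.values[np.ix_(perm, perm)]) >= r_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return r_obs, p
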