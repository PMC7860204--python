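"""SSR marker polymorphism and population-diversity statistics.

Multilocus genotype (MLG) identification with missing-tolerant matching,
genotype accumulation curves, per-locus indices (Na, Ne, I, Ho, He, Fis,
Fst, PIC) and per-stratum diversity summaries with private and diagnostic
alleles and Nm gene-flow estimates.

Estimator conventions follow the GenAlEx defaults: He = 1 - sum p^2
(uncorrected), Fis = (He - Ho)/He, Fst = (Ht - mean Hs)/Ht on stratum-mean
frequencies (Nei's Gst form); a Weir-Cockerham theta estimator is available
separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

PIC_INFORMATIVE_THRESHOLD = 0.5

FreqTable = dict[str, dict[str, dict[int, float]]]  # stratum -> locus -> allele -> freq


# ---------------------------------------------------------------------------
# multilocus genotypes


@dataclass
class MLGAssignment:
    """Accession -> MLG id mapping with one representative per MLG."""

    mlg_of: dict[str, int]
    representatives: dict[int, str]

    @property
    def n_mlgs(self) -> int:
        return len(self.representatives)

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for acc, m in self.mlg_of.items():
            out.setdefault(m, []).append(acc)
        return out


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _sorted_calls(g: GenotypeMatrix) -> np.ndarray:
    """Calls with each diploid pair sorted so (a,b) == (b,a)."""
    return np.sort(g.calls, axis=2)


def identify_mlgs(
    g: GenotypeMatrix, missing_policy: str = "wildcard"
) -> MLGAssignment:
    """Group accessions into multilocus genotypes.

    With ``missing_policy="wildcard"`` a missing locus matches anything and
    MLGs are the transitive closure of pairwise matches (the regrouping used
    by MLG-census tools); ``"strict"`` requires both calls present and equal
    at every locus.
    """
    g = g.drop_all_missing()
    calls = _sorted_calls(g)
    miss = g.missing_mask()
    n = g.n_accessions
    uf = _UnionFind(n)
    for i in range(n - 1):
        eq = (calls[i + 1 :] == calls[i]).all(axis=2)
        if missing_policy == "wildcard":
            comparable = ~(miss[i + 1 :] | miss[i])
            match = (eq | ~comparable).all(axis=1)
        elif missing_policy == "strict":
            present = ~(miss[i + 1 :] | miss[i])
            match = (eq & present).all(axis=1)
        else:
            raise ValueError(f"unknown missing_policy {missing_policy!r}")
        for j in np.flatnonzero(match):
            uf.union(i, i + 1 + int(j))
    roots: dict[int, int] = {}
    mlg_of: dict[str, int] = {}
    reps: dict[int, str] = {}
    for i, acc in enumerate(g.accession_ids):
        r = uf.find(i)
        if r not in roots:
            roots[r] = len(roots) + 1
            reps[roots[r]] = acc
        mlg_of[acc] = roots[r]
    return MLGAssignment(mlg_of, reps)


def genotype_accumulation(
    g: GenotypeMatrix,
    n_perm: int = 100,
    seed: int = 0,
    missing_policy: str = "strict",
) -> pd.DataFrame:
    """MLG counts for random locus subsets of size 1 .. L-1.

    Matching defaults to ``strict`` here (unlike the census): under the
    wildcard rule an accession missing one locus of a small subset bridges
    otherwise distinct genotypes and the curve loses its monotonicity.  On a
    panel without missing data the two policies coincide.

    Each of the *n_perm* permutations draws a random locus order and counts
    distinct MLGs along its nested prefixes (sampling without replacement),
    so every permutation's curve is monotone.  The curve is flagged
    saturated (``.attrs["saturated"]``) when the median count at L-1 loci
    equals the full-panel MLG count — the markers reach their maximal
    differentiation before the last locus is added.
    """
    L = g.n_loci
    if L < 2:
        raise ValueError("genotype accumulation requires >= 2 loci")
    rng = np.random.default_rng(seed)
    full = identify_mlgs(g, missing_policy).n_mlgs
    counts_by_size = np.empty((n_perm, L - 1), dtype=int)
    for p in range(n_perm):
        order = rng.permutation(L)
        for size in range(1, L):
            # accessions fully missing on a small subset are expected; the
            # per-subset drop warnings would be pure noise
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                counts_by_size[p, size - 1] = identify_mlgs(
                    g.subset_loci(order[:size]), missing_policy
                ).n_mlgs
    rows = []
    for size in range(1, L):
        counts = counts_by_size[:, size - 1]
        rows.append(
            {
                "n_loci": size,
                "median_mlgs": float(np.median(counts)),
                "min_mlgs": int(counts.min()),
                "max_mlgs": int(counts.max()),
                "mean_mlgs": float(counts.mean()),
            }
        )
    df = pd.DataFrame(rows).set_index("n_loci")
    df.attrs["full_mlg_count"] = full
    df.attrs["saturated"] = bool(df["median_mlgs"].iloc[-1] == full)
    return df


# ---------------------------------------------------------------------------
# allele frequencies and per-locus indices


def _locus_freqs(calls_j: np.ndarray) -> dict[int, float]:
    """Allele frequencies over non-missing copies of one locus column."""
    copies = calls_j.ravel()
    copies = copies[copies != MISSING]
    if copies.size == 0:
        return {}
    vals, counts = np.unique(copies, return_counts=True)
    return {int(v): c / copies.size for v, c in zip(vals, counts)}


def allele_frequencies(
    g: GenotypeMatrix, strata: Mapping[str, Sequence[str]] | None = None
) -> FreqTable:
    """Per stratum/locus allele frequencies over non-missing copies.

    With no strata the single stratum ``"all"`` covers the panel.  A locus
    entirely missing within a stratum yields an empty vector.
    """
    strata = strata or {"all": list(g.accession_ids)}
    out: FreqTable = {}
    for label, accs in strata.items():
        sub = g.subset(accs)
        out[label] = {
            loc: _locus_freqs(sub.calls[:, j, :])
            for j, loc in enumerate(g.locus_names)
        }
    return out


def pic(freqs: Mapping[int, float] | Sequence[float]) -> float:
    """Polymorphic information content PIC = 1 - sum f_i^2 on pooled
    frequencies; markers with PIC >= 0.5 are conventionally informative."""
    p = np.asarray(
        list(freqs.values()) if isinstance(freqs, Mapping) else freqs, float
    )
    if p.size == 0:
        raise ValueError("empty frequency vector")
    return float(1.0 - (p**2).sum())


def _shannon(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum()) if p.size else 0.0


def _he(p: np.ndarray) -> float:
    return float(1.0 - (p**2).sum()) if p.size else 0.0


def _ho(calls_j: np.ndarray) -> float:
    present = calls_j[:, 0] != MISSING
    if present.sum() == 0:
        return np.nan
    het = calls_j[present, 0] != calls_j[present, 1]
    return float(het.mean())


def per_locus_fst(
    g: GenotypeMatrix, strata: Mapping[str, Sequence[str]]
) -> pd.Series:
    """Nei Gst per locus: (Ht - mean_s Hs)/Ht, Ht from the unweighted mean
    of stratum frequency vectors.  NaN where Ht = 0."""
    table = allele_frequencies(g, strata)
    out = {}
    for j, loc in enumerate(g.locus_names):
        vecs = [table[s][loc] for s in table if table[s][loc]]
        if not vecs:
            out[loc] = np.nan
            continue
        support = sorted({a for v in vecs for a in v})
        mat = np.array([[v.get(a, 0.0) for a in support] for v in vecs])
        hs = np.mean([_he(row) for row in mat])
        ht = _he(mat.mean(axis=0))
        out[loc] = np.nan if ht == 0 else (ht - hs) / ht
    return pd.Series(out, name="fst")


def weir_cockerham_fst(
    g: GenotypeMatrix, strata: Mapping[str, Sequence[str]]
) -> float:
    """Weir-Cockerham (1984) multiallelic theta across all loci."""
    subs = {label: g.subset(accs) for label, accs in strata.items()}
    num = den = 0.0
    for j in range(g.n_loci):
        alleles = np.unique(g.calls[:, j, :])
        alleles = alleles[alleles != MISSING]
        ns, ps, hs = [], [], []
        for sub in subs.values():
            cj = sub.calls[:, j, :]
            present = cj[:, 0] != MISSING
            n_i = int(present.sum())
            if n_i == 0:
                continue
            cj = cj[present]
            p_i = np.array([(cj == a).sum() / (2 * n_i) for a in alleles])
            h_i = np.array(
                [
                    np.mean((cj[:, 0] != cj[:, 1]) & ((cj == a).any(axis=1)))
                    for a in alleles
                ]
            )
            ns.append(n_i)
            ps.append(p_i)
            hs.append(h_i)
        r = len(ns)
        if r < 2:
            continue
        ns_arr = np.array(ns, float)
        nbar = ns_arr.mean()
        if nbar <= 1:
            continue
        nc = (r * nbar - (ns_arr**2).sum() / (r * nbar)) / (r - 1)
        P = np.array(ps)  # (r, A)
        H = np.array(hs)
        pbar = (ns_arr[:, None] * P).sum(axis=0) / (r * nbar)
        s2 = (ns_arr[:, None] * (P - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (ns_arr[:, None] * H).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - s2 * (r - 1) / r
            - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
        num += a.sum()
        den += (a + b + c).sum()
    return float(num / den) if den != 0 else np.nan


def locus_indices(
    g: GenotypeMatrix,
    strata: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Per-locus N, Na, Ne, I, Ho, He, Fis, PIC (pooled panel) and, when
    strata are given, the Gst-form Fst."""
    rows = []
    for j, loc in enumerate(g.locus_names):
        cj = g.calls[:, j, :]
        present = cj[:, 0] != MISSING
        freqs = _locus_freqs(cj)
        p = np.array(list(freqs.values()))
        he = _he(p)
        ho = _ho(cj)
        rows.append(
            {
                "locus": loc,
                "N": int(present.sum()),
                "Na": len(freqs),
                "Ne": float(1.0 / (p**2).sum()) if p.size else np.nan,
                "I": _shannon(p),
                "Ho": ho,
                "He": he,
                "Fis": (he - ho) / he if he > 0 else np.nan,
                "PIC": pic(freqs) if freqs else np.nan,
            }
        )
    df = pd.DataFrame(rows).set_index("locus")
    df["informative"] = df["PIC"] >= PIC_INFORMATIVE_THRESHOLD
    if strata is not None:
        df["Fst"] = per_locus_fst(g, strata)
    return df


# ---------------------------------------------------------------------------
# per-stratum diversity and private / diagnostic alleles


def nm_from_fst(fst: float) -> float:
    """Gene flow Nm = 0.25 (1 - Fst)/Fst (infinite at Fst = 0)."""
    if np.isnan(fst):
        return np.nan
    if fst == 0:
        return np.inf
    return 0.25 * (1.0 - fst) / fst


def private_and_diagnostic_alleles(
    freq_table: FreqTable,
    diagnostic_major: float = 0.70,
    diagnostic_minor: float = 0.30,
) -> tuple[pd.Series, pd.DataFrame]:
    """Private alleles (present in exactly one stratum) and diagnostic
    alleles (frequency > 70% in one stratum and < 30% in every other)."""
    strata = list(freq_table)
    if len(strata) < 2:
        raise ValueError("need >= 2 strata")
    loci = list(next(iter(freq_table.values())))
    pa = {s: 0 for s in strata}
    da_rows = []
    for loc in loci:
        support = sorted(
            {a for s in strata for a in freq_table[s][loc]}
        )
        for a in support:
            f = np.array([freq_table[s][loc].get(a, 0.0) for s in strata])
            present = f > 0
            if present.sum() == 1:
                pa[strata[int(np.argmax(present))]] += 1
            for i, s in enumerate(strata):
                others = np.delete(f, i)
                if f[i] > diagnostic_major and (others < diagnostic_minor).all():
                    da_rows.append(
                        {
                            "stratum": s,
                            "locus": loc,
                            "allele": a,
                            "frequency": float(f[i]),
                        }
                    )
    return (
        pd.Series(pa, name="private_alleles"),
        pd.DataFrame(da_rows, columns=["stratum", "locus", "allele", "frequency"]),
    )


def stratum_diversity(
    g: GenotypeMatrix, strata: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Per-stratum diversity record: mean (SE over loci) of Na, Ne, I, Ho,
    He, Fis; percent polymorphic loci; private/diagnostic allele counts; MLG
    count.  ``.attrs`` carries the across-strata mean Fst, the derived gene
    flow Nm = 0.25 (1 - Fst)/Fst, and the diagnostic-allele table.
    """
    freq_table = allele_frequencies(g, strata)
    multi = len(strata) >= 2
    if multi:
        pa, da = private_and_diagnostic_alleles(freq_table)
    rows = []
    for label, accs in strata.items():
        sub = g.subset(accs)
        per_locus = locus_indices(sub)
        na = per_locus["Na"].astype(float)
        row = {"stratum": label, "n_accessions": sub.n_accessions}
        row["n_mlgs"] = identify_mlgs(sub).n_mlgs
        for col in ("Na", "Ne", "I", "Ho", "He", "Fis"):
            vals = per_locus[col].dropna()
            row[col] = float(vals.mean()) if len(vals) else np.nan
            row[f"{col}_se"] = (
                float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
            )
        row["percent_polymorphic"] = float(100.0 * (na >= 2).mean())
        if multi:
            row["n_private"] = int(pa[label])
            row["n_diagnostic"] = int((da["stratum"] == label).sum())
        rows.append(row)
    df = pd.DataFrame(rows).set_index("stratum")
    if multi:
        fst = per_locus_fst(g, strata).dropna()
        mean_fst = float(fst.mean()) if len(fst) else np.nan
        df.attrs["mean_fst"] = mean_fst
        df.attrs["nm"] = float(nm_from_fst(mean_fst))
        df.attrs["diagnostic_alleles"] = da
    else:
        warnings.warn("single stratum: Fst and Nm undefined", stacklevel=2)
        df.attrs["mean_fst"] = np.nan
        df.attrs["nm"] = np.nan
    return df
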