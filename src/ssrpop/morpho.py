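"""Phenotypic diversity of coded spike/grain traits.

Shannon-Weaver diversity H = -sum p ln p over phenotypic classes, normalised
to H' = H / ln(S) in [0, 1]; PCA on the coded trait matrix; per-cluster trait
means; and one-way ANOVA with compact letter displays for mean separation.

By default S (the class count entering Hmax) is the number of classes
observed in the whole collection for that trait, so a trait segregating all
its observed classes evenly reaches H' = 1; pass ``s_mode="theoretical"`` to
normalise by the descriptor universe instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import TraitMatrix


@dataclass(frozen=True)
class ShannonResult:
    trait: str
    stratum: str
    H: float
    H_prime: float
    S: int


def class_frequencies(codes: np.ndarray) -> dict[int, float]:
    """Relative frequencies of the observed classes in a code vector."""
    vals, counts = np.unique(np.asarray(codes), return_counts=True)
    total = counts.sum()
    return {int(v): c / total for v, c in zip(vals, counts)}


def shannon_weaver(
    freqs: Mapping[int, float], S: int, trait: str = "", stratum: str = ""
) -> ShannonResult:
    """H = -sum p ln p and H' = H/ln(S); H' defined 0 when S <= 1."""
    n_obs = sum(1 for p in freqs.values() if p > 0)
    if S < n_obs:
        raise ValueError(f"S={S} < observed class count {n_obs}")
    p = np.array([v for v in freqs.values() if v > 0], dtype=float)
    H = float(-(p * np.log(p)).sum()) if p.size else 0.0
    if S <= 1 or n_obs <= 1:
        H_prime = 0.0
    else:
        H_prime = H / np.log(S)
    return ShannonResult(trait, stratum, H, H_prime, S)


def _class_counts(traits: TraitMatrix, s_mode: str) -> list[int]:
    if s_mode == "observed":
        return [
            int(len(np.unique(traits.codes[:, j])))
            for j in range(len(traits.traits))
        ]
    if s_mode == "theoretical":
        return [len(t.universe) for t in traits.traits]
    raise ValueError(f"unknown s_mode {s_mode!r}")


def diversity_table(
    traits: TraitMatrix,
    strata: Mapping[str, Sequence[str]] | None = None,
    s_mode: str = "observed",
    include_collection: bool = True,
) -> pd.DataFrame:
    """H' per trait (rows) x stratum (columns), with row/column means.

    *strata* maps stratum name -> accession ids.  Empty strata are omitted
    with a warning.  The final row ``mean`` averages H' over the 12 traits;
    the final column ``mean`` averages each trait over strata (excluding the
    whole-collection column).
    """
    import warnings

    S = _class_counts(traits, s_mode)
    columns: dict[str, list[float]] = {}
    names = traits.trait_names

    def _col(sub: TraitMatrix, label: str) -> list[float]:
        return [
            shannon_weaver(
                class_frequencies(sub.codes[:, j]), S[j], names[j], label
            ).H_prime
            for j in range(len(names))
        ]

    if include_collection:
        columns["collection"] = _col(traits, "collection")
    strata = strata or {}
    order = []
    for label, accs in strata.items():
        accs = [a for a in accs if a in traits.accession_ids]
        if not accs:
            warnings.warn(f"empty stratum {label!r} omitted", stacklevel=2)
            continue
        columns[label] = _col(traits.subset(accs), label)
        order.append(label)
    df = pd.DataFrame(columns, index=names)
    stratum_cols = order if order else list(df.columns)
    df["mean"] = df[stratum_cols].mean(axis=1)
    df.loc["mean"] = df.mean(axis=0)
    return df


def trait_pca(
    traits: TraitMatrix, scale: bool = False
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """PCA of the centred coded traits (covariance by default).

    Returns (scores, percent_variance, loadings).  ``scale=True`` switches
    to the correlation matrix (unit-variance codes).
    """
    X = traits.codes.astype(float)
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    n = X.shape[0]
    if n < 3:
        raise ValueError("PCA requires at least 3 accessions")
    cov = X.T @ X / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0.0, None), evecs[:, order]
    total = evals.sum()
    pct = 100.0 * evals / total if total > 0 else np.zeros_like(evals)
    axes = [f"PC{i + 1}" for i in range(len(evals))]
    scores = pd.DataFrame(X @ evecs, index=traits.accession_ids, columns=axes)
    loadings = pd.DataFrame(evecs, index=traits.trait_names, columns=axes)
    return scores, pd.Series(pct, index=axes, name="percent_variance"), loadings


def cluster_trait_means(
    traits: TraitMatrix, membership: Mapping[str, str]
) -> pd.DataFrame:
    """Mean class code per trait per cluster: mean = sum(n_i * C_i) / N.

    *membership* maps accession id -> cluster label.  Accessions without a
    label are ignored.
    """
    rows = {}
    clusters = sorted(set(membership.values()))
    frame = traits.to_frame()
    for cl in clusters:
        accs = [a for a in traits.accession_ids if membership.get(a) == cl]
        rows[cl] = frame.loc[accs].mean(axis=0)
    return pd.DataFrame(rows).T


def _letters_from_nonsig(nonsig: np.ndarray, order: np.ndarray) -> list[str]:
    """Compact letter display from a boolean 'not significantly different'
    matrix; groups are lettered along *order* (ascending mean)."""
    k = nonsig.shape[0]
    intervals: list[tuple[int, int]] = []
    for a in range(k):
        b = a
        while b + 1 < k and all(
            nonsig[order[x], order[y]]
            for x in range(a, b + 2)
            for y in range(x + 1, b + 2)
        ):
            b += 1
        intervals.append((a, b))
    # keep maximal intervals only
    maximal = [
        iv for iv in intervals
        if not any(o != iv and o[0] <= iv[0] and iv[1] <= o[1] for o in intervals)
    ]
    seen: list[tuple[int, int]] = []
    for iv in maximal:
        if iv not in seen:
            seen.append(iv)
    letters = [""] * k
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for li, (a, b) in enumerate(seen):
        for pos in range(a, b + 1):
            letters[order[pos]] += alphabet[li % len(alphabet)]
    return letters


def compare_means(
    traits: TraitMatrix,
    membership: Mapping[str, str],
    alpha: float = 0.05,
    method: str = "anova",
) -> pd.DataFrame:
    """Per-trait mean separation across clusters at level *alpha*.

    One-way ANOVA on the integer codes (``method="anova"``) or
    Kruskal-Wallis (``method="kruskal"``), followed by Tukey-style pairwise
    comparisons; clusters sharing no letter differ significantly.  Returns a
    table with one row per cluster, columns ``<trait>`` (mean) and
    ``<trait>_letters``, plus per-trait p-values in ``.attrs["pvalues"]``.
    """
    clusters = sorted(set(membership.values()))
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters")
    frame = traits.to_frame()
    groups_idx = {
        cl: [a for a in traits.accession_ids if membership.get(a) == cl]
        for cl in clusters
    }
    for cl, accs in groups_idx.items():
        if len(accs) < 2:
            raise ValueError(f"cluster {cl!r} has fewer than 2 accessions")
    out = pd.DataFrame(index=clusters)
    pvals = {}
    for trait in traits.trait_names:
        samples = [frame.loc[groups_idx[cl], trait].to_numpy(float) for cl in clusters]
        means = np.array([s.mean() for s in samples])
        pooled_var = np.concatenate([s - s.mean() for s in samples]).var()
        if pooled_var == 0 and np.ptp(means) == 0:
            p_global = 1.0
            nonsig = np.ones((len(clusters), len(clusters)), bool)
        elif pooled_var == 0:
            p_global = 0.0
            nonsig = np.equal.outer(means, means)
        else:
            if method == "kruskal":
                p_global = stats.kruskal(*samples).pvalue
            else:
                p_global = stats.f_oneway(*samples).pvalue
            tk = stats.tukey_hsd(*samples)
            nonsig = tk.pvalue > alpha
        order = np.argsort(means, kind="stable")
        letters = _letters_from_nonsig(nonsig, order)
        out[trait] = means
        out[trait + "_letters"] = letters
        pvals[trait] = float(p_global)
    out.attrs["pvalues"] = pvals
    return out
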