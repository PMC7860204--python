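"""One-level analysis of molecular variance (AMOVA).

Partitions pairwise squared genotypic distances into among- and
within-stratum components.  With N accessions in k strata of sizes n_g:

    SS_total  = sum_{i<j} d2_ij / N
    SS_within = sum_g sum_{i<j in g} d2_ij / n_g
    SS_among  = SS_total - SS_within

    MS = SS / df with df_among = k - 1, df_within = N - k
    sigma2_within = MS_within
    sigma2_among  = (MS_among - MS_within) / n0,
                    n0 = (N - sum n_g^2 / N) / (k - 1)

Phi_ST = sigma2_among / (sigma2_among + sigma2_within); its significance
comes from permuting accessions across strata (one-sided on Phi).  Negative
among components are truncated to zero for the percentage column but kept
raw in a diagnostics column.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .distances import DistanceMatrix


@dataclass
class AMOVAResult:
    """df/SS/MS/variance-component table with Phi and permutation p."""

    table: pd.DataFrame
    phi: float
    p_value: float
    n_perm: int
    stratification: str = ""

    @property
    def percent_among(self) -> float:
        return float(self.table.loc["Among", "percent"])

    @property
    def percent_within(self) -> float:
        return float(self.table.loc["Within", "percent"])


def _ss_decomposition(
    d2: np.ndarray, codes: np.ndarray, sizes: np.ndarray
) -> tuple[float, float]:
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for gi, ng in enumerate(sizes):
        idx = np.flatnonzero(codes == gi)
        if len(idx) < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / ng
    return float(ss_total), float(ss_within)


def amova_one_level(
    d2: DistanceMatrix,
    strata: Mapping[str, Sequence[str]],
    n_perm: int = 999,
    seed: int = 0,
    stratification: str = "",
) -> AMOVAResult:
    """One-level AMOVA of a squared-distance matrix over a stratification.

    *strata* maps stratum label -> accession ids; accessions not listed are
    excluded.  Requires k >= 2 strata.
    """
    labels = [a for accs in strata.values() for a in accs]
    if len(set(labels)) != len(labels):
        raise ValueError("strata overlap")
    k = len(strata)
    if k < 2:
        raise ValueError("AMOVA requires >= 2 strata")
    sub = d2.reorder(labels)
    codes = np.concatenate(
        [np.full(len(accs), gi) for gi, accs in enumerate(strata.values())]
    )
    sizes = np.array([len(accs) for accs in strata.values()], float)
    n = int(sizes.sum())
    dmat = sub.values

    ss_total, ss_within = _ss_decomposition(dmat, codes, sizes)
    ss_among = ss_total - ss_within
    df_among, df_within, df_total = k - 1, n - k, n - 1
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    n0 = (n - (sizes**2).sum() / n) / (k - 1)
    var_within = ms_within
    var_among_raw = (ms_among - ms_within) / n0
    var_among = max(var_among_raw, 0.0)
    total_var = var_among + var_within
    phi = var_among / total_var if total_var > 0 else 0.0

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        pt, pw = _ss_decomposition(dmat, codes[perm], sizes)
        pa = pt - pw
        p_var_among = (pa / df_among - pw / df_within) / n0
        p_var_within = pw / df_within
        tot = max(p_var_among, 0.0) + p_var_within
        p_phi = max(p_var_among, 0.0) / tot if tot > 0 else 0.0
        if p_phi >= phi:
            count += 1
    p_value = (1 + count) / (1 + n_perm)

    table = pd.DataFrame(
        {
            "df": [df_among, df_within, df_total],
            "SS": [ss_among, ss_within, ss_total],
            "MS": [ms_among, ms_within, np.nan],
            "est_var": [var_among, var_within, total_var],
            "est_var_raw": [var_among_raw, var_within, var_among_raw + var_within],
            "percent": [
                100.0 * var_among / total_var if total_var > 0 else 0.0,
                100.0 * var_within / total_var if total_var > 0 else 100.0,
                100.0,
            ],
        },
        index=["Among", "Within", "Total"],
    )
    return AMOVAResult(table, float(phi), float(p_value), n_perm, stratification)


def amova_report(results: Sequence[AMOVAResult]) -> pd.DataFrame:
    """Stack AMOVA tables for several stratifications into one table."""
    if not results:
        raise ValueError("no AMOVA results")
    blocks = []
    for res in results:
        block = res.table.copy()
        block.insert(0, "stratification", res.stratification)
        block.insert(1, "source", block.index)
        block["Phi"] = [res.phi, np.nan, np.nan]
        block["p"] = [res.p_value, np.nan, np.nan]
        blocks.append(block.reset_index(drop=True))
    return pd.concat(blocks, ignore_index=True)
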