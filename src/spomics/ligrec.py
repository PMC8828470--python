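"""Permutation-based ligand-receptor interaction test across cluster pairs.

For every annotated (ligand, receptor) pair and every ordered cluster pair
(sender, receiver), the observed statistic is the symmetric mean

    m = ( mean ligand expression over sender cells
        + mean receptor expression over receiver cells ) / 2,

where a multi-subunit complex is reduced per cell to the minimum (or mean)
of its subunits.  Cluster labels are reshuffled ``n_perms`` times to build a
null distribution of m, and p = (1 + #{m_perm >= m_obs}) / (1 + n_perms).
Cluster pairs where either complex is expressed in too small a fraction of
its cluster's cells keep their mean but get p = NaN (the expression filter);
Benjamini-Hochberg adjustment runs over the tested (non-NaN) hypotheses.

The input matrix is used as-is — no internal normalization; log-normalized
expression is the recommended input.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .datamodel import InteractionTable, SpatialDataset

__all__ = ["ligrec_test", "read_interactions"]


def read_interactions(path) -> InteractionTable:
    """Read a ligand-receptor table from CSV with columns ``source,target``.

    Multi-subunit complexes are underscore-joined gene lists
    (``"L1_L2"``); duplicate rows are dropped, subunit order preserved.
    """
    df = pd.read_csv(path, comment="#")
    if not {"source", "target"} <= set(df.columns):
        raise ValueError(f"interaction file {path} must have columns source,target")
    sources = [InteractionTable.parse_complex(s) for s in df["source"]]
    targets = [InteractionTable.parse_complex(t) for t in df["target"]]
    return InteractionTable(sources=sources, targets=targets)


def _complex_values(
    dataset: SpatialDataset, complexes: list[tuple[str, ...]], policy: str
) -> np.ndarray:
    """Per-cell complex expression, n_obs x n_complexes (min or mean over subunits)."""
    X = dataset.dense_X()
    var_pos = {g: i for i, g in enumerate(dataset.var_ids)}
    out = np.empty((dataset.n_obs, len(complexes)))
    for ci, cplx in enumerate(complexes):
        cols = X[:, [var_pos[g] for g in cplx]]
        out[:, ci] = cols.min(axis=1) if policy == "min" else cols.mean(axis=1)
    return out


def ligrec_test(
    dataset: SpatialDataset,
    label_key: str,
    interactions: InteractionTable,
    n_perms: int = 1000,
    seed: int = 0,
    complex_policy: str = "min",
    expr_frac_threshold: float = 0.1,
) -> pd.DataFrame:
    """Permutation test of ligand-receptor expression across cluster pairs.

    Returns a long-format table with one row per (interaction, sender,
    receiver): columns ``source``, ``target``, ``sender``, ``receiver``,
    ``mean``, ``pvalue``, ``pvalue_adj``.  Identical seeds give bit-identical
    results.

    Parameters
    ----------
    complex_policy
        How a multi-subunit complex is reduced per cell: "min" (the limiting
        subunit) or "mean".
    expr_frac_threshold
        Minimum fraction of a cluster's cells with complex expression > 0
        for the pair to be tested; below it the mean is reported but the
        p-value is NaN.
    """
    if complex_policy not in ("min", "mean"):
        raise ValueError(f"complex_policy must be 'min' or 'mean', got {complex_policy!r}")
    codes, cats = dataset.label_codes(label_key)
    k = len(cats)
    if k < 2:
        raise ValueError("ligrec test needs at least 2 clusters")

    present = set(dataset.var_ids)
    kept_src, kept_tgt, dropped = [], [], []
    for s, t in interactions:
        if all(g in present for g in s + t):
            kept_src.append(s)
            kept_tgt.append(t)
        else:
            dropped.append((s, t))
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} interaction(s) with genes absent from the dataset",
            stacklevel=2,
        )
    if not kept_src:
        raise ValueError("no interactions left after filtering for present genes")
    n_int = len(kept_src)

    lig = _complex_values(dataset, kept_src, complex_policy)  # n_obs x n_int
    rec = _complex_values(dataset, kept_tgt, complex_policy)

    n = dataset.n_obs
    onehot = np.zeros((k, n))
    onehot[codes, np.arange(n)] = 1.0
    cluster_sizes = onehot.sum(axis=1)
    if np.any(cluster_sizes == 0):
        empty = [c for c, s in zip(cats, cluster_sizes) if s == 0]
        raise ValueError(f"empty cluster level(s): {empty}")
    group_mean = onehot / cluster_sizes[:, None]  # k x n, rows sum to 1

    mean_lig = group_mean @ lig  # k x n_int
    mean_rec = group_mean @ rec
    # observed statistic per (sender s, receiver r, interaction)
    m_obs = 0.5 * (mean_lig[:, None, :] + mean_rec[None, :, :])  # k x k x n_int

    frac_lig = group_mean @ (lig > 0)  # fraction of expressing cells
    frac_rec = group_mean @ (rec > 0)
    tested = (frac_lig[:, None, :] >= expr_frac_threshold) & (
        frac_rec[None, :, :] >= expr_frac_threshold
    )

    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(m_obs)
    for _ in range(n_perms):
        perm = rng.permutation(n)
        gm = group_mean[:, perm]
        ml = gm @ lig
        mr = gm @ rec
        m_perm = 0.5 * (ml[:, None, :] + mr[None, :, :])
        exceed += m_perm >= m_obs
    pvals = (1.0 + exceed) / (1.0 + n_perms)
    pvals[~tested] = np.nan

    flat_p = pvals.ravel()
    padj = np.full_like(flat_p, np.nan)
    ok = ~np.isnan(flat_p)
    if ok.any():
        padj[ok] = multipletests(flat_p[ok], method="fdr_bh")[1]
    padj = padj.reshape(pvals.shape)

    labels = [("_".join(s), "_".join(t)) for s, t in zip(kept_src, kept_tgt)]
    rows = []
    for ii, (src, tgt) in enumerate(labels):
        for si in range(k):
            for ri in range(k):
                rows.append(
                    {
                        "source": src,
                        "target": tgt,
                        "sender": cats[si],
                        "receiver": cats[ri],
                        "mean": m_obs[si, ri, ii],
                        "pvalue": pvals[si, ri, ii],
                        "pvalue_adj": padj[si, ri, ii],
                    }
                )
    out = pd.DataFrame(rows)
    out.attrs["n_perms"] = n_perms
    out.attrs["seed"] = seed
    out.attrs["complex_policy"] = complex_policy
    return out
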