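"""Peak-to-gene correlation links, gene ranking, and DORC scores.

Links are Pearson correlations between peak accessibility and gene
expression across cells or cell aggregates, restricted to peaks within
+/- 500 kb of a gene's transcription start site, with two-sided p-values
from the t-distribution and Benjamini-Hochberg FDR computed across all
tested pairs genome-wide. High-confidence links require r >= 0.1 (signed:
anti-correlated pairs are excluded) and FDR < 1e-4.

A gene's DORC ("domain of regulatory chromatin") score in a cell is the
sum of its linked peaks' fragment-count-normalized accessibility:
``score_c = sum_p x_pc / F_c`` over linked peaks within the window, where
``F_c`` is the cell's genome-wide unique fragment total -- so the score is
invariant under joint scaling of counts and fragment totals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

LINK_COLUMNS = ["peak_id", "gene", "r", "p", "fdr", "distance"]


def make_cell_aggregates(
    embedding: np.ndarray,
    k_neighbors: int,
    n_groups: int,
    max_overlap: float = 0.8,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    max_resample: int = 1000,
) -> list[np.ndarray]:
    """Sample overlapping k-nearest-neighbor cell groups from an embedding.

    Each group is the ``k_neighbors`` nearest neighbors (self included) of
    a randomly sampled seed cell; a group whose Jaccard overlap with any
    accepted group exceeds ``max_overlap`` is discarded and resampled.
    Deterministic under a fixed seed.
    """
    from sklearn.neighbors import NearestNeighbors

    emb = np.asarray(embedding, dtype=float)
    n_cells = emb.shape[0]
    if n_cells < k_neighbors:
        raise ValueError(f"{n_cells} cells < k_neighbors={k_neighbors}")
    if rng is None:
        rng = np.random.default_rng(seed)
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(emb)
    groups: list[np.ndarray] = []
    member_sets: list[set] = []
    attempts = 0
    while len(groups) < n_groups:
        if attempts > max_resample * n_groups:
            raise RuntimeError("could not sample enough sufficiently "
                               "non-overlapping aggregates")
        attempts += 1
        seed_cell = int(rng.integers(0, n_cells))
        idx = nn.kneighbors(emb[seed_cell:seed_cell + 1],
                            return_distance=False)[0]
        s = set(int(i) for i in idx)
        ok = all(
            len(s & m) / len(s | m) <= max_overlap for m in member_sets
        )
        if ok:
            groups.append(np.sort(idx))
            member_sets.append(s)
    return groups


def aggregate_matrix(x: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Sum a features-by-cells matrix into features-by-aggregates."""
    return np.column_stack([x[:, g].sum(axis=1) for g in groups])


def _normalize_log(x: np.ndarray) -> np.ndarray:
    """Depth-normalize columns to the mean total, then log1p."""
    totals = x.sum(axis=0).astype(float)
    totals[totals == 0] = 1.0
    scale = totals.mean() / totals
    return np.log1p(x * scale)


def compute_peak_gene_links(
    acc: np.ndarray,
    expr: np.ndarray,
    peaks: pd.DataFrame,
    tss: pd.DataFrame,
    window: int = 500_000,
    r_min: float = 0.1,
    fdr_max: float = 1e-4,
    aggregates: list[np.ndarray] | None = None,
    return_all: bool = False,
) -> pd.DataFrame:
    """Correlate accessibility with expression for nearby peak/gene pairs.

    ``acc`` is peaks-by-cells, ``expr`` genes-by-cells (row order matching
    ``peaks`` / ``tss``). ``peaks`` needs contig/start/end/peak_id; ``tss``
    needs gene/contig/tss/strand (``tss`` already strand-resolved: the
    start coordinate for + genes, the end for - genes). When
    ``aggregates`` is given both matrices are first summed per group.
    Pairs are tested when |peak midpoint - TSS| <= ``window`` on the same
    contig; zero-variance rows are skipped. Retained links satisfy
    ``r >= r_min`` and ``fdr < fdr_max`` unless ``return_all``.
    """
    if aggregates is not None:
        acc = aggregate_matrix(acc, aggregates)
        expr = aggregate_matrix(expr, aggregates)
    n = acc.shape[1]
    if n != expr.shape[1]:
        raise ValueError("accessibility and expression disagree on cell count")
    if n < 3:
        raise ValueError("need >= 3 aggregates for a correlation")
    acc = np.asarray(acc, dtype=float)
    expr = np.asarray(expr, dtype=float)
    acc_n = _normalize_log(acc)
    expr_n = _normalize_log(expr)

    mid = ((peaks["start"].to_numpy() + peaks["end"].to_numpy()) // 2)
    peak_contig = peaks["contig"].to_numpy()
    peak_ids = peaks["peak_id"].to_numpy()
    # zero variance in either the raw or the normalized values disqualifies
    acc_sd = np.minimum(acc_n.std(axis=1), acc.std(axis=1))
    expr_sd = np.minimum(expr_n.std(axis=1), expr.std(axis=1))

    rows = []
    for gi, g in enumerate(tss.itertuples(index=False)):
        if expr_sd[gi] == 0:
            continue
        dist = mid - int(g.tss)
        sel = np.flatnonzero((peak_contig == g.contig) & (np.abs(dist) <= window)
                             & (acc_sd > 0))
        for pi in sel:
            a = acc_n[pi]
            b = expr_n[gi]
            r = float(np.corrcoef(a, b)[0, 1])
            rows.append((peak_ids[pi], g.gene, r, int(dist[pi])))
    if not rows:
        return pd.DataFrame(columns=LINK_COLUMNS)
    df = pd.DataFrame(rows, columns=["peak_id", "gene", "r", "distance"])
    r = df["r"].to_numpy()
    r_c = np.clip(r, -0.9999999999, 0.9999999999)
    t = r_c * np.sqrt((n - 2) / (1.0 - r_c**2))
    df["p"] = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    df["fdr"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    df = df[LINK_COLUMNS]
    if return_all:
        return df.reset_index(drop=True)
    keep = (df["r"] >= r_min) & (df["fdr"] < fdr_max)
    return df[keep].reset_index(drop=True)


def rank_genes_by_links(
    links: pd.DataFrame,
    window: int = 50_000,
) -> pd.DataFrame:
    """Per-gene counts of linked peaks near the TSS, rank-ordered.

    Each peak is first assigned to its single lowest-FDR gene (ties broken
    by smaller absolute distance, then lexical gene id); counts then
    include only links within +/- ``window`` of the TSS. Returns columns
    gene / n_links / rank (dense ranks, ties share a rank).
    """
    if links.empty:
        return pd.DataFrame(columns=["gene", "n_links", "rank"])
    lk = links.copy()
    lk["_absd"] = lk["distance"].abs()
    lk = lk.sort_values(["peak_id", "fdr", "_absd", "gene"], kind="stable")
    best = lk.drop_duplicates("peak_id", keep="first")
    near = best[best["_absd"] <= window]
    counts = near.groupby("gene").size().rename("n_links").reset_index()
    counts = counts.sort_values(["n_links", "gene"], ascending=[False, True],
                                kind="stable").reset_index(drop=True)
    counts["rank"] = counts["n_links"].rank(method="min", ascending=False).astype(int)
    return counts


def dorc_scores(
    acc: np.ndarray,
    frag_totals: np.ndarray,
    links: pd.DataFrame,
    gene: str,
    peaks: pd.DataFrame,
    tss: pd.DataFrame,
    window: int = 500_000,
) -> np.ndarray:
    """Per-cell DORC score for one gene.

    Sums fragment-normalized accessibility (``x_pc / F_c``) over the
    gene's linked peaks whose midpoints lie within +/- ``window`` of its
    TSS. A gene with no links yields an all-zero vector; a gene absent
    from the TSS table raises.
    """
    trow = tss[tss["gene"] == gene]
    if trow.empty:
        raise KeyError(f"gene {gene!r} absent from TSS table")
    g = trow.iloc[0]
    F = np.asarray(frag_totals, dtype=float)
    if np.any(F <= 0):
        raise ValueError("non-positive per-cell fragment total")
    gene_links = links[links["gene"] == gene]
    mid = (peaks["start"].to_numpy() + peaks["end"].to_numpy()) // 2
    sel = peaks["peak_id"].isin(set(gene_links["peak_id"])).to_numpy()
    sel &= (peaks["contig"].to_numpy() == g["contig"])
    sel &= np.abs(mid - int(g["tss"])) <= window
    if not sel.any():
        return np.zeros(acc.shape[1], dtype=float)
    return np.asarray(acc, dtype=float)[sel].sum(axis=0) / F
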