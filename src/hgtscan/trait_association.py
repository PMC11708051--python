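"""Association between lifestyle traits and per-genome HGT abundance.

Three complementary tests:

* **Permutation RDA** — redundancy analysis of a per-genome HGT response
  (count, or a donor-composition matrix) constrained on one categorical
  trait; significance from the pseudo-F under row permutation of the
  response, with the add-one convention ``p = (1 + #{F* >= F}) / (1 + B)``.
* **PGLS** — generalized least squares with Brownian-motion covariance
  (C_ij = shared root-to-tip path length on the species tree), testing the
  trait's coefficients jointly with an F test.  HGT counts are usually
  log1p-transformed first to stabilize variance.
* **Pearson correlation** between HGT counts and total gene content — the
  "does genome size drive HGT" check.

Genomes missing the tested trait are dropped per-trait (complete case).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AssociationResult:
    trait: str
    method: str  # "RDA_PERM" | "PGLS"
    statistic: float
    p_value: float
    n_used: int
    coefficients: dict[str, float] = field(default_factory=dict)


class UntestableTraitError(ValueError):
    pass


def _one_hot(trait: pd.Series) -> pd.DataFrame:
    """Dummy-code a categorical trait, dropping the (alphabetically) first
    level as reference."""
    levels = sorted(trait.dropna().unique())
    if len(levels) < 2:
        raise UntestableTraitError(
            f"untestable trait {trait.name!r}: fewer than 2 observed levels"
        )
    return pd.DataFrame(
        {f"{trait.name}[{lv}]": (trait == lv).astype(float) for lv in levels[1:]},
        index=trait.index,
    )


# ------------------------------------------------------------------- RDA

def rda_permutation_test(
    response: pd.Series | pd.DataFrame,
    trait: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
) -> AssociationResult:
    """Permutation test of the RDA pseudo-F for one categorical trait.

    ``response`` is a per-genome HGT summary (single count column or a
    composition matrix), rows aligned with ``trait``.  The response is
    column-centered; F = (explained SS / df1) / (residual SS / df2) from the
    least-squares projection onto the one-hot design.  Rows of the response
    are permuted; deterministic for a fixed seed.
    """
    y = response.to_frame() if isinstance(response, pd.Series) else response
    keep = trait.notna()
    y = y.loc[keep].astype(float)
    t = trait.loc[keep]
    n = len(y)
    if n < 3:
        raise UntestableTraitError(
            f"trait {trait.name!r}: fewer than 3 genomes with data"
        )
    X = _one_hot(t).to_numpy()
    Y = y.to_numpy()
    Yc = Y - Y.mean(axis=0, keepdims=True)
    Xc = X - X.mean(axis=0, keepdims=True)
    df1 = np.linalg.matrix_rank(Xc)
    df2 = n - df1 - 1
    if df2 <= 0:
        raise UntestableTraitError(f"trait {trait.name!r}: no residual df")
    # projection onto the centered design's column space
    P = Xc @ np.linalg.pinv(Xc.T @ Xc) @ Xc.T

    ss_tot = float((Yc ** 2).sum())
    if ss_tot == 0.0:
        return AssociationResult(
            trait=str(trait.name), method="RDA_PERM", statistic=0.0,
            p_value=1.0, n_used=n,
        )

    def pseudo_f(Ymat: np.ndarray) -> float:
        fit = P @ Ymat
        ss_fit = float((fit ** 2).sum())
        ss_res = ss_tot - ss_fit
        if ss_res <= 1e-12 * ss_tot:  # design explains everything
            return float("inf")
        return (ss_fit / df1) / (ss_res / df2)

    f_obs = pseudo_f(Yc)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if pseudo_f(Yc[perm]) >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return AssociationResult(
        trait=str(trait.name), method="RDA_PERM", statistic=float(f_obs),
        p_value=float(p), n_used=n,
    )


# ------------------------------------------------------------------ PGLS

def phylo_covariance(tree: dendropy.Tree, genomes: list[str]) -> np.ndarray:
    """Brownian-motion covariance: C_ij = shared root-to-tip path length.

    Tip labels of ``tree`` must cover every genome; raises with the list of
    absentees otherwise.
    """
    label_to_leaf = {}
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is not None:
            label_to_leaf[leaf.taxon.label] = leaf
    missing = [g for g in genomes if g not in label_to_leaf]
    if missing:
        raise ValueError(f"genomes absent from species tree: {missing}")

    # node depths from the root
    depth: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        edge = node.edge.length or 0.0
        depth[id(node)] = (depth[id(parent)] if parent is not None else 0.0) + edge

    # ancestor chains per tip
    chains: dict[str, list] = {}
    for g in genomes:
        chain = []
        node = label_to_leaf[g]
        while node is not None:
            chain.append(id(node))
            node = node.parent_node
        chains[g] = chain

    n = len(genomes)
    C = np.zeros((n, n))
    for i, gi in enumerate(genomes):
        seti = set(chains[gi])
        C[i, i] = depth[chains[gi][0]]
        for j in range(i + 1, n):
            mrca = next(a for a in chains[genomes[j]] if a in seti)
            C[i, j] = C[j, i] = depth[mrca]
    return C


def pgls_fit(
    tree: dendropy.Tree,
    y: pd.Series,
    trait: pd.Series,
    log_transform: bool = True,
) -> AssociationResult:
    """PGLS of a per-genome HGT count on one trait under Brownian motion.

    ``y`` is indexed by genome id (log1p applied when ``log_transform``);
    ``trait`` may be categorical (one-hot, reference dropped) or numeric.
    The overall trait p comes from the GLS F test of the trait coefficients
    against the intercept-only model.  On a star phylogeny (no shared
    branches) the fit reduces to ordinary least squares.
    """
    keep = trait.notna() & y.notna()
    yv = y.loc[keep].astype(float)
    t = trait.loc[keep]
    genomes = list(yv.index)
    n = len(genomes)
    if n < 3:
        raise UntestableTraitError(f"trait {trait.name!r}: fewer than 3 genomes")
    if log_transform:
        yv = np.log1p(yv)

    if pd.api.types.is_numeric_dtype(t):
        design = t.astype(float).to_frame(name=str(trait.name))
        if design.iloc[:, 0].nunique() < 2:
            raise UntestableTraitError(f"untestable trait {trait.name!r}")
    else:
        design = _one_hot(t)
    X = np.column_stack([np.ones(n), design.to_numpy()])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"singular design for trait {trait.name!r}")

    C = phylo_covariance(tree, genomes)
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        # zero-length branches can make C numerically singular
        L = np.linalg.cholesky(C + 1e-8 * np.trace(C) / n * np.eye(n))
    Xw = np.linalg.solve(L, X)
    yw = np.linalg.solve(L, yv.to_numpy())

    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss1 = float(resid @ resid)
    # intercept-only GLS model
    X0w = Xw[:, :1]
    b0, *_ = np.linalg.lstsq(X0w, yw, rcond=None)
    r0 = yw - X0w @ b0
    rss0 = float(r0 @ r0)

    q = X.shape[1] - 1
    dfe = n - X.shape[1]
    if dfe <= 0:
        raise UntestableTraitError(f"trait {trait.name!r}: no residual df")
    scale = max(rss0, 1e-300)
    if rss1 / scale < 1e-12:
        if (rss0 - rss1) / scale < 1e-12:  # constant response: nothing to fit
            f, p = 0.0, 1.0
        else:  # perfect fit: smallest representable p
            f, p = float("inf"), float(np.finfo(float).tiny)
    else:
        f = ((rss0 - rss1) / q) / (rss1 / dfe)
        p = max(float(stats.f.sf(f, q, dfe)), float(np.finfo(float).tiny))
    coeffs = {"intercept": float(beta[0])}
    coeffs.update({c: float(b) for c, b in zip(design.columns, beta[1:])})
    return AssociationResult(
        trait=str(trait.name), method="PGLS", statistic=float(f),
        p_value=p, n_used=n, coefficients=coeffs,
    )


# ----------------------------------------------------------- correlations

def hgt_gene_content_correlation(
    hgt_counts: pd.Series, total_genes: pd.Series
) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between per-genome HGT counts
    and total gene content."""
    joined = pd.concat([hgt_counts, total_genes], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 genomes")
    x = joined.iloc[:, 0].to_numpy(float)
    y = joined.iloc[:, 1].to_numpy(float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def group_summaries(hgt_counts: pd.Series, trait: pd.Series) -> pd.DataFrame:
    """Per-level n, median and interquartile range of HGT counts for one
    trait, levels ranked by descending median (ties broken by level name)."""
    df = pd.concat([hgt_counts.rename("count"), trait.rename("level")], axis=1)
    df = df.dropna()
    rows = []
    for level, grp in df.groupby("level"):
        q1, med, q3 = np.percentile(grp["count"], [25, 50, 75])
        rows.append({
            "level": level, "n": len(grp), "median": float(med),
            "iqr": float(q3 - q1),
        })
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    return out.sort_values(
        ["median", "level"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
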