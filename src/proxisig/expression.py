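"""Count normalization, DEG calling and DEG summary structures.

The DEG test is a negative-binomial exact test conditioned on the per-group
pseudo-count sums, with tagwise method-of-moments dispersions shrunk toward
the common dispersion and median-of-ratios library-size normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as st
from scipy.special import logsumexp

from proxisig.errors import ConfigurationError, DegenerateDataError

GROUPS = ("treated", "control")


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Gene x sample integer counts with sample annotations.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, genes as rows, samples as columns.
    annotations
        DataFrame indexed by sample id with columns ``tissue``, ``group``
        (``treated``/``control``) and ``replicate``.
    gene_lengths
        Optional Series of per-gene transcript lengths in bases (required for
        FPKM normalization).
    """

    counts: pd.DataFrame
    annotations: pd.DataFrame
    gene_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ConfigurationError("counts: negative values present")
        if not np.allclose(self.counts.values, np.round(self.counts.values)):
            raise ConfigurationError("counts: non-integer values present")
        missing = set(self.counts.columns) - set(self.annotations.index)
        if missing:
            raise ConfigurationError(
                f"annotations: samples without annotation: {sorted(missing)[:5]}"
            )
        for col in ("tissue", "group", "replicate"):
            if col not in self.annotations.columns:
                raise ConfigurationError(f"annotations: missing column {col!r}")
        bad = set(self.annotations["group"]) - set(GROUPS)
        if bad:
            raise ConfigurationError(f"annotations: unknown group labels {sorted(bad)}")
        if self.gene_lengths is not None:
            if (self.gene_lengths <= 0).any():
                raise ConfigurationError("gene_lengths: non-positive lengths present")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def tissues(self) -> list[str]:
        return sorted(self.annotations.loc[self.samples, "tissue"].unique())

    def subset_tissue(self, tissue: str) -> "CountMatrix":
        keep = [s for s in self.samples if self.annotations.at[s, "tissue"] == tissue]
        if not keep:
            raise ConfigurationError(f"tissue: no samples annotated as {tissue!r}")
        return CountMatrix(
            counts=self.counts[keep],
            annotations=self.annotations.loc[keep],
            gene_lengths=self.gene_lengths,
        )


@dataclass
class FPKMMatrix:
    """Gene x sample FPKM values."""

    values: pd.DataFrame

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass
class DEGTable:
    """Per-tissue differential-expression results.

    ``rows`` has one row per gene with columns ``log2fc``, ``p_value`` and
    ``direction`` (``up``/``down``/``ns``); ``alpha`` records the threshold
    used for direction assignment.
    """

    tissue: str
    rows: pd.DataFrame
    alpha: float = 0.05

    def gene_sets(self) -> dict[str, set[str]]:
        """Up / down / both DEG gene sets at the recorded alpha."""
        up = set(self.rows.index[self.rows["direction"] == "up"])
        down = set(self.rows.index[self.rows["direction"] == "down"])
        return {"up": up, "down": down, "both": up | down}

    def n_up(self) -> int:
        return int((self.rows["direction"] == "up").sum())

    def n_down(self) -> int:
        return int((self.rows["direction"] == "down").sum())


@dataclass
class DEGSummary:
    """Cross-tissue DEG summary: counts, sharing histogram, cosine clustering."""

    per_tissue: pd.DataFrame  # index tissue, columns up/down/total
    union_size: int
    sharing_histogram: dict[int, int]  # k tissues -> number of genes
    cosine: pd.DataFrame  # tissue x tissue
    modules: dict[str, str]  # tissue -> Mod_up | Mod_down | Mod_inbetween
    linkage: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "per_tissue": self.per_tissue.to_dict(orient="index"),
            "union_size": self.union_size,
            "sharing_histogram": {str(k): v for k, v in self.sharing_histogram.items()},
            "cosine": self.cosine.round(6).to_dict(orient="index"),
            "modules": self.modules,
        }


@dataclass
class ClusterResult:
    """Hierarchical clustering + PCA of expression profiles."""

    linkage: np.ndarray
    sample_ids: list[str]
    newick: str
    pca_scores: pd.DataFrame  # samples x PCs
    explained_variance_ratio: np.ndarray


@dataclass
class CentralityComparison:
    """Rank-sum comparison of centralities between DEG and non-DEG nodes."""

    node_values: pd.DataFrame  # node x (pagerank, betweenness, is_deg)
    medians: dict[str, dict[str, float]]  # metric -> {deg, non_deg}
    p_values: dict[str, float]  # metric -> rank-sum p
    n_deg_in_network: int


# ---------------------------------------------------------------------------
# FPKM
# ---------------------------------------------------------------------------


def fpkm_normalize(cm: CountMatrix) -> FPKMMatrix:
    """FPKM(g, s) = counts(g, s) * 1e9 / (total_counts(s) * length(g))."""
    if cm.gene_lengths is None:
        raise ConfigurationError("gene_lengths: required for FPKM normalization")
    missing = [g for g in cm.genes if g not in cm.gene_lengths.index]
    if missing:
        raise ConfigurationError(
            f"gene_lengths: missing lengths for {len(missing)} genes, "
            f"e.g. {missing[:5]}"
        )
    totals = cm.counts.sum(axis=0)
    zero_depth = list(totals.index[totals == 0])
    if zero_depth:
        raise ConfigurationError(f"counts: zero-depth samples {zero_depth}")
    lengths = cm.gene_lengths.loc[cm.genes].astype(float)
    vals = (
        cm.counts.astype(float)
        .div(totals, axis=1)
        .div(lengths, axis=0)
        * 1e9
    )
    return FPKMMatrix(values=vals)


# ---------------------------------------------------------------------------
# DEG calling: NB exact test
# ---------------------------------------------------------------------------


def _size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, normalized to geometric mean 1.

    Falls back to total-count scaling when too few genes are expressed in all
    samples.
    """
    pos = (counts > 0).all(axis=1)
    if pos.sum() >= 10:
        logc = np.log(counts[pos].astype(float))
        log_geomean = logc.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logc - log_geomean, axis=0))
    else:
        totals = counts.sum(axis=0).astype(float)
        if (totals == 0).any():
            raise ConfigurationError("counts: zero-depth sample in DEG test")
        sf = totals / np.exp(np.mean(np.log(totals)))
    return sf / np.exp(np.mean(np.log(sf)))


def _moment_dispersions(
    norm: np.ndarray, is_a: np.ndarray, sf: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-gene method-of-moments NB dispersions and a common dispersion.

    Tagwise estimates use within-group residuals so that real group
    differences do not inflate them:
    E[SSE] = sum_groups (n_g - 1)(m_g + phi * m_g^2).

    The common dispersion solves the Pearson pseudo-likelihood equation
    sum of squared Pearson residuals = residual degrees of freedom, with
    per-sample variances m/s_j + phi * m^2 so that size-factor scaling of
    the Poisson part is accounted for.
    """
    groups = [(norm[:, is_a], sf[is_a]), (norm[:, ~is_a], sf[~is_a])]
    sse = np.zeros(norm.shape[0])
    lin = np.zeros(norm.shape[0])
    quad = np.zeros(norm.shape[0])
    for x, _ in groups:
        n = x.shape[1]
        m = x.mean(axis=1)
        sse += ((x - m[:, None]) ** 2).sum(axis=1)
        lin += (n - 1) * m
        quad += (n - 1) * m ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        tagwise = (sse - lin) / quad
    tagwise[~np.isfinite(tagwise)] = 0.0
    expressed = quad > 0

    if not expressed.any():
        return tagwise, 0.0

    def pearson_excess(phi: float) -> float:
        total = 0.0
        df = 0.0
        for x, s in groups:
            n = x.shape[1]
            m_all = x.mean(axis=1)
            keep = expressed & (m_all > 0)
            m = m_all[keep]
            resid = (x[keep] - m[:, None]) ** 2
            var = m[:, None] / s[None, :] + phi * (m ** 2)[:, None]
            total += float((resid / var).sum())
            df += (n - 1) * len(m)
        return total - df

    lo, hi = 0.0, 10.0
    if pearson_excess(lo) <= 0:
        common = 0.0
    elif pearson_excess(hi) >= 0:
        common = hi
    else:
        for _ in range(60):
            mid = (lo + hi) / 2.0
            if pearson_excess(mid) > 0:
                lo = mid
            else:
                hi = mid
        common = (lo + hi) / 2.0
    return tagwise, common


def _exact_test_pvalue(
    s_a: float, s_b: float, n_a: int, n_b: int, phi: float
) -> float:
    """Two-sided conditional NB exact test p-value.

    Conditions on the total pseudo-count S = s_a + s_b; under the null the
    group-A sum follows the distribution proportional to
    NB(k; n_a*mu, phi/n_a) * NB(S-k; n_b*mu, phi/n_b). The two-sided p-value
    sums all outcomes no more probable than the observed one.
    """
    # round each group sum separately so that swapping groups mirrors exactly
    k_obs = int(round(s_a))
    total = k_obs + int(round(s_b))
    if total == 0:
        return 1.0
    k = np.arange(total + 1)
    mu = total / (n_a + n_b)
    if phi < 1e-8:
        # Poisson limit: conditional law is exactly binomial
        lp = st.binom.logpmf(k, total, n_a / (n_a + n_b))
    else:
        r_a = n_a / phi
        r_b = n_b / phi
        m_a = n_a * mu
        m_b = n_b * mu
        lp = st.nbinom.logpmf(k, r_a, r_a / (r_a + m_a)) + st.nbinom.logpmf(
            total - k, r_b, r_b / (r_b + m_b)
        )
        lp -= logsumexp(lp)
    p = float(np.exp(lp[lp <= lp[k_obs] + 1e-10]).sum())
    return min(p, 1.0)


def detect_degs(
    cm: CountMatrix,
    tissue: str,
    alpha: float = 0.05,
    prior_weight: float = 20.0,
) -> DEGTable:
    """Call treated-vs-control DEGs for one tissue with an NB exact test.

    Parameters
    ----------
    cm
        Count matrix covering at least the requested tissue.
    tissue
        Tissue identifier to subset on.
    alpha
        Raw p-value threshold for direction assignment.
    prior_weight
        Degrees-of-freedom weight given to the common dispersion when
        shrinking tagwise dispersions.
    """
    if not 0 <= alpha <= 1:
        raise ConfigurationError("alpha: must be in [0, 1]")
    sub = cm.subset_tissue(tissue)
    grp = sub.annotations.loc[sub.samples, "group"].values
    is_a = grp == "treated"
    n_a, n_b = int(is_a.sum()), int((~is_a).sum())
    if n_a < 2 or n_b < 2:
        raise ConfigurationError(
            f"tissue {tissue!r}: need >=2 replicates per group, "
            f"got treated={n_a}, control={n_b}"
        )
    counts = sub.counts.values
    sf = _size_factors(counts)
    norm = counts / sf[None, :]
    tagwise, common = _moment_dispersions(norm, is_a, sf)
    df_resid = (n_a - 1) + (n_b - 1)
    phi = np.clip(
        (prior_weight * common + df_resid * tagwise) / (prior_weight + df_resid),
        0.0,
        None,
    )

    mean_a = norm[:, is_a].mean(axis=1)
    mean_b = norm[:, ~is_a].mean(axis=1)
    log2fc = np.log2((mean_a + 0.5) / (mean_b + 0.5))

    sum_a = norm[:, is_a].sum(axis=1)
    sum_b = norm[:, ~is_a].sum(axis=1)
    pvals = np.ones(counts.shape[0])
    for i in range(counts.shape[0]):
        if sum_a[i] + sum_b[i] == 0:
            pvals[i] = 1.0
            log2fc[i] = 0.0
            continue
        pvals[i] = _exact_test_pvalue(sum_a[i], sum_b[i], n_a, n_b, phi[i])

    direction = np.where(
        (pvals < alpha) & (log2fc > 0),
        "up",
        np.where((pvals < alpha) & (log2fc < 0), "down", "ns"),
    )
    rows = pd.DataFrame(
        {"log2fc": log2fc, "p_value": pvals, "direction": direction},
        index=sub.genes,
    )
    return DEGTable(tissue=tissue, rows=rows, alpha=alpha)


# ---------------------------------------------------------------------------
# DEG summary
# ---------------------------------------------------------------------------


def _signed_indicator(table: DEGTable, union: pd.Index) -> np.ndarray:
    v = pd.Series(0.0, index=union)
    sets = table.gene_sets()
    v.loc[v.index.intersection(list(sets["up"]))] = 1.0
    v.loc[v.index.intersection(list(sets["down"]))] = -1.0
    return v.values


def summarize_degs(tables: Sequence[DEGTable]) -> DEGSummary:
    """Cross-tissue DEG summary.

    Cosine similarity between tissues is computed on signed indicator vectors
    (+1 up, -1 down, 0 otherwise) over the union of all DEGs; tissue modules
    come from cutting the average-linkage dendrogram of (1 - cosine) at three
    clusters and labelling clusters by mean signed DEG balance.
    """
    if not tables:
        raise ConfigurationError("tables: need at least one DEGTable")
    tissues = [t.tissue for t in tables]
    if len(set(tissues)) != len(tissues):
        raise ConfigurationError("tables: duplicate tissue ids")

    union: set[str] = set()
    per_tissue = {}
    for t in tables:
        sets = t.gene_sets()
        union |= sets["both"]
        per_tissue[t.tissue] = {
            "up": len(sets["up"]),
            "down": len(sets["down"]),
            "total": len(sets["both"]),
        }
    union_idx = pd.Index(sorted(union))
    per_tissue_df = pd.DataFrame(per_tissue).T.loc[tissues]

    multiplicity = pd.Series(0, index=union_idx)
    for t in tables:
        both = t.gene_sets()["both"]
        multiplicity.loc[multiplicity.index.intersection(list(both))] += 1
    hist: dict[int, int] = (
        multiplicity.value_counts().sort_index().to_dict() if len(union_idx) else {}
    )
    hist = {int(k): int(v) for k, v in hist.items()}

    vectors = np.array(
        [_signed_indicator(t, union_idx) for t in tables]
    )  # tissues x genes
    norms = np.linalg.norm(vectors, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cos = (vectors @ vectors.T) / np.outer(norms, norms)
    cos[~np.isfinite(cos)] = 0.0
    np.fill_diagonal(cos, 1.0)
    cosine = pd.DataFrame(cos, index=tissues, columns=tissues)

    modules: dict[str, str] = {}
    linkage = None
    if len(tissues) >= 3:
        dist = 1.0 - cos
        dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
        np.fill_diagonal(dist, 0.0)
        condensed = dist[np.triu_indices(len(tissues), k=1)]
        linkage = sch.linkage(condensed, method="average")
        labels = sch.fcluster(linkage, t=3, criterion="maxclust")
        balance = {}
        for lab in np.unique(labels):
            members = [tissues[i] for i in range(len(tissues)) if labels[i] == lab]
            vals = []
            for m in members:
                up, down = per_tissue[m]["up"], per_tissue[m]["down"]
                vals.append((up - down) / (up + down) if up + down else 0.0)
            balance[lab] = float(np.mean(vals))
        order = sorted(balance, key=lambda lab: balance[lab])
        names: dict[int, str] = {}
        if len(order) == 3:
            names = {order[0]: "Mod_down", order[1]: "Mod_inbetween", order[2]: "Mod_up"}
        elif len(order) == 2:
            names = {order[0]: "Mod_down", order[1]: "Mod_up"}
        else:
            names = {order[0]: "Mod_inbetween"}
        modules = {tissues[i]: names[labels[i]] for i in range(len(tissues))}

    return DEGSummary(
        per_tissue=per_tissue_df,
        union_size=len(union_idx),
        sharing_histogram=hist,
        cosine=cosine,
        modules=modules,
        linkage=linkage,
    )


# ---------------------------------------------------------------------------
# clustering / PCA
# ---------------------------------------------------------------------------


def _linkage_to_newick(linkage: np.ndarray, labels: Sequence[str]) -> str:
    tree = sch.to_tree(linkage)

    def build(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left = build(node.left)
        right = build(node.right)
        dl = max(node.dist - node.left.dist, 0.0)
        dr = max(node.dist - node.right.dist, 0.0)
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return build(tree) + ";"


def cluster_profiles(
    fm: FPKMMatrix, gene_subset: Iterable[str], n_components: int = 2
) -> ClusterResult:
    """Cluster samples on log2(FPKM+1) and compute PCA scores.

    Hierarchical clustering uses correlation distance with average linkage;
    PCA is run on the same matrix, centred per gene.
    """
    genes = [g for g in gene_subset if g in fm.genes]
    if not genes:
        raise ConfigurationError("gene_subset: empty after intersection with matrix")
    if fm.values.shape[1] < 3:
        raise ConfigurationError("samples: need at least 3 samples")
    x = np.log2(fm.values.loc[genes].values + 1.0)  # genes x samples
    centered = x - x.mean(axis=1, keepdims=True)
    if not np.any(np.abs(centered) > 1e-12):
        raise DegenerateDataError("expression matrix constant across samples")

    # correlation distance between sample profiles
    samples = list(fm.samples)
    xs = x.T  # samples x genes
    xs_c = xs - xs.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(xs_c, axis=1)
    if (norms == 0).any():
        raise DegenerateDataError("constant sample profile; correlation undefined")
    corr = (xs_c @ xs_c.T) / np.outer(norms, norms)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    condensed = dist[np.triu_indices(len(samples), k=1)]
    linkage = sch.linkage(condensed, method="average")
    newick = _linkage_to_newick(linkage, samples)

    # PCA on gene-centred matrix; samples are observations
    u, s, _ = np.linalg.svd(centered.T, full_matrices=False)
    k = max(2, min(n_components, len(s)))
    k = min(k, len(s))
    scores = u[:, :k] * s[:k]
    var = s ** 2
    evr = var / var.sum() if var.sum() > 0 else var
    pca = pd.DataFrame(
        scores, index=samples, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return ClusterResult(
        linkage=linkage,
        sample_ids=samples,
        newick=newick,
        pca_scores=pca,
        explained_variance_ratio=evr[:k],
    )


# ---------------------------------------------------------------------------
# centrality comparison
# ---------------------------------------------------------------------------


def compare_centrality(net, deg_genes: Iterable[str]) -> CentralityComparison:
    """Compare PageRank (damping 0.85) and betweenness of DEG vs non-DEG nodes.

    ``net`` may be a :class:`proxisig.network.SignalingNetwork` or any
    networkx graph whose nodes are gene symbols.
    """
    import networkx as nx

    if isinstance(net, nx.Graph):
        graph = net
    else:
        graph = net.graph
    degs = {str(g).upper() for g in deg_genes}
    nodes = list(graph.nodes())
    in_net = degs & set(nodes)
    if not in_net:
        raise ConfigurationError("deg_genes: none map into the network")
    pagerank = nx.pagerank(graph, alpha=0.85)
    betweenness = nx.betweenness_centrality(graph)
    df = pd.DataFrame(
        {
            "pagerank": pd.Series(pagerank),
            "betweenness": pd.Series(betweenness),
        }
    )
    df["is_deg"] = [n in in_net for n in df.index]
    medians = {}
    p_values = {}
    for metric in ("pagerank", "betweenness"):
        a = df.loc[df["is_deg"], metric].values
        b = df.loc[~df["is_deg"], metric].values
        medians[metric] = {
            "deg": float(np.median(a)),
            "non_deg": float(np.median(b)) if len(b) else float("nan"),
        }
        if len(b) and (np.ptp(np.concatenate([a, b])) > 0):
            p_values[metric] = float(
                st.mannwhitneyu(a, b, alternative="two-sided").pvalue
            )
        else:
            p_values[metric] = 1.0
    return CentralityComparison(
        node_values=df,
        medians=medians,
        p_values=p_values,
        n_deg_in_network=len(in_net),
    )
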