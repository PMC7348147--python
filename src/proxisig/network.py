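"""Drug-target network proximity with permutation null, FDR and consensus.

The proximity of a DEG set D to a drug-target set T is the mean over DEGs of
the shortest-path hop distance to the nearest target:

    dist(D, T) = (1/m) * sum_i min_j sp(D_i, T_j)

Significance is judged against redraws of equally sized random target sets
from the network; the screen runs the six (DEG-kind x target-source)
combinations per drug and tissue and applies the two-source consensus rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path
from statsmodels.stats.multitest import multipletests

from proxisig.errors import ConfigurationError, ParseError

DEG_KINDS = ("up", "down", "both")


@dataclass
class DrugTargetSet:
    """One drug's target genes from one annotation source."""

    drug: str
    targets: frozenset[str]
    source_db: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "targets", frozenset(str(t).upper() for t in self.targets)
        )


@dataclass
class ProximityResult:
    """One (drug, tissue, DEG-kind, source) proximity test."""

    drug: str
    tissue: str
    deg_set_kind: str
    source_db: str
    observed_dist: float
    null_dists: np.ndarray
    empirical_p: float
    n_deg_in_network: int
    n_targets_in_network: int
    fdr: float = float("nan")


@dataclass
class ConsensusCall:
    """Two-source consensus for one (drug, tissue) pair."""

    drug: str
    tissue: str
    supporting: dict[str, list[str]]  # source_db -> significant DEG kinds
    retained: bool


class SignalingNetwork:
    """Directed signalling network over uppercase gene symbols.

    Self-loops are dropped and duplicate edges collapsed at construction.
    Edges flagged as undirected are stored as reciprocal arcs.
    """

    def __init__(self, edges: Iterable[tuple[str, str, bool]]):
        g = nx.DiGraph()
        for u, v, directed in edges:
            u, v = str(u).upper(), str(v).upper()
            if u == v:
                continue
            g.add_edge(u, v)
            if not directed:
                g.add_edge(v, u)
        if g.number_of_nodes() == 0:
            raise ParseError("network: no edges after loading")
        self.graph: nx.DiGraph = g
        self._nodes: list[str] = sorted(g.nodes())
        self._index: dict[str, int] = {n: i for i, n in enumerate(self._nodes)}
        self._adj_cache: dict[str, csr_matrix] = {}
        self._penalty_cache: dict[str, float] = {}

    # -- construction ------------------------------------------------------

    @classmethod
    def from_edgelist_tsv(cls, path: str | Path) -> "SignalingNetwork":
        """Load from TSV with columns source, target[, directed]."""
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        if df.shape[1] < 2:
            raise ParseError(f"{path}: expected >=2 columns (source, target)")
        cols = [c.lower() for c in df.columns]
        df.columns = cols
        src = df.columns[0] if "source" not in cols else "source"
        tgt = df.columns[1] if "target" not in cols else "target"
        if "directed" in cols:
            directed = (
                df["directed"].str.lower().isin(["1", "true", "yes", "t"]).values
            )
        else:
            directed = np.ones(len(df), dtype=bool)
        return cls(zip(df[src], df[tgt], directed))

    @classmethod
    def from_graphml(cls, path: str | Path) -> "SignalingNetwork":
        g = nx.read_graphml(path)
        directed = g.is_directed()
        return cls((u, v, directed) for u, v in g.edges())

    # -- basic properties --------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        return self._nodes

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def summary(self) -> dict:
        und = self.graph.to_undirected(as_view=True)
        comps = list(nx.connected_components(und))
        return {
            "nodes": self.n_nodes,
            "edges": self.n_edges,
            "largest_component": max(len(c) for c in comps),
        }

    # -- distances ---------------------------------------------------------

    def _adjacency(self, mode: str) -> csr_matrix:
        if mode not in ("directed", "undirected"):
            raise ConfigurationError(f"distance mode: unknown {mode!r}")
        if mode not in self._adj_cache:
            rows, cols = [], []
            for u, v in self.graph.edges():
                rows.append(self._index[u])
                cols.append(self._index[v])
            n = self.n_nodes
            adj = csr_matrix(
                (np.ones(len(rows)), (rows, cols)), shape=(n, n)
            )
            if mode == "undirected":
                adj = adj.maximum(adj.T)
            self._adj_cache[mode] = adj
        return self._adj_cache[mode]

    def distances_from(self, genes: Sequence[str], mode: str) -> np.ndarray:
        """Hop distances from each gene (row) to every network node (column)."""
        idx = [self._index[g] for g in genes]
        adj = self._adjacency(mode)
        return shortest_path(
            adj, directed=(mode == "directed"), unweighted=True, indices=idx
        )

    def unreachable_penalty(self, mode: str) -> float:
        """Finite stand-in distance: diameter of the largest component + 1.

        Undirected mode uses the largest connected component; directed mode
        the largest strongly connected component (directed hops can exceed
        this across components — the penalty is applied identically to
        observed and null scores, which keeps the comparison fair).
        """
        if mode not in self._penalty_cache:
            adj = self._adjacency(mode)
            directed = mode == "directed"
            n_comp, labels = connected_components(
                adj, directed=directed, connection="strong" if directed else "weak"
            )
            sizes = np.bincount(labels)
            comp = int(np.argmax(sizes))
            members = np.where(labels == comp)[0]
            if len(members) < 2:
                self._penalty_cache[mode] = 1.0
                return 1.0
            sub = adj[members][:, members]
            d = shortest_path(sub, directed=directed, unweighted=True)
            diameter = float(d[np.isfinite(d)].max())
            self._penalty_cache[mode] = diameter + 1.0
        return self._penalty_cache[mode]

    def degrees(self) -> np.ndarray:
        und = self.graph.to_undirected(as_view=True)
        return np.array([und.degree(n) for n in self._nodes], dtype=float)


# ---------------------------------------------------------------------------
# proximity scoring
# ---------------------------------------------------------------------------


def _intersect(net: SignalingNetwork, genes: Iterable[str], side: str) -> list[str]:
    found = sorted({str(g).upper() for g in genes} & set(net.nodes))
    if not found:
        raise ConfigurationError(f"{side}: no genes map into the network")
    return found


def _score(dmat: np.ndarray, target_idx: np.ndarray, penalty: float | None) -> float:
    sub = dmat[:, target_idx].min(axis=1)
    if penalty is None:  # drop unreachable DEGs
        sub = sub[np.isfinite(sub)]
        if len(sub) == 0:
            return float("nan")
    else:
        sub = np.where(np.isfinite(sub), sub, penalty)
    return float(sub.mean())


def drug_deg_proximity(
    net: SignalingNetwork,
    degs: Iterable[str],
    targets: Iterable[str],
    mode: str = "undirected",
    drop_unreachable: bool = False,
) -> float:
    """dist(D, T): mean over in-network DEGs of hop distance to nearest target."""
    d = _intersect(net, degs, "degs")
    t = _intersect(net, targets, "targets")
    dmat = net.distances_from(d, mode)
    penalty = None if drop_unreachable else net.unreachable_penalty(mode)
    t_idx = np.array([net._index[g] for g in t])
    return _score(dmat, t_idx, penalty)


def _null_draws(
    net: SignalingNetwork,
    size: int,
    n_perm: int,
    rng: np.random.Generator,
    degree_matched: bool,
    target_idx: np.ndarray,
) -> np.ndarray:
    n = net.n_nodes
    if degree_matched:
        deg = net.degrees()
        bins = np.floor(np.log2(deg + 1.0)).astype(int)
        by_bin = {b: np.where(bins == b)[0] for b in np.unique(bins)}
        t_bins = bins[target_idx]
        draws = np.empty((n_perm, size), dtype=int)
        for j, b in enumerate(t_bins):
            pool = by_bin[b]
            draws[:, j] = rng.choice(pool, size=n_perm, replace=True)
        return draws
    draws = np.empty((n_perm, size), dtype=int)
    for i in range(n_perm):
        draws[i] = rng.choice(n, size=size, replace=False)
    return draws


def proximity_permutation_test(
    net: SignalingNetwork,
    degs: Iterable[str],
    targets: Iterable[str],
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    mode: str = "undirected",
    degree_matched_null: bool = False,
    drop_unreachable: bool = False,
    drug: str = "",
    tissue: str = "",
    deg_set_kind: str = "both",
    source_db: str = "",
    tie_break: str = "conservative",
) -> ProximityResult:
    """Permutation test of dist(D, T) against random target sets.

    The null redraws ``|T ∩ net|`` nodes uniformly from the whole network
    ``n_perm`` times; the empirical p-value uses the add-one estimator
    ``(1 + #{null <= observed}) / (n_perm + 1)``.

    The proximity statistic is lattice-valued (a mean of integer hop counts),
    so observed/null ties are common. ``tie_break="conservative"`` (default)
    counts every tie against the observed value, which makes the p-value
    valid but super-uniform under the null. ``tie_break="random"`` places the
    observed value at a uniformly random rank among its ties (seeded), which
    makes the null distribution of the p-value exactly uniform on the grid
    k/(n_perm+1).
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm: must be >= 1")
    d = _intersect(net, degs, "degs")
    t = _intersect(net, targets, "targets")
    if len(t) >= net.n_nodes:
        raise ConfigurationError("targets: as large as the whole network")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    dmat = net.distances_from(d, mode)
    penalty = None if drop_unreachable else net.unreachable_penalty(mode)
    t_idx = np.array([net._index[g] for g in t])
    observed = _score(dmat, t_idx, penalty)
    draws = _null_draws(net, len(t), n_perm, rng, degree_matched_null, t_idx)
    null = np.array([_score(dmat, row, penalty) for row in draws])
    finite_null = null[np.isfinite(null)]
    if tie_break not in ("conservative", "random"):
        raise ConfigurationError(f"tie_break: unknown {tie_break!r}")
    if not np.isfinite(observed):
        n_le = len(finite_null)
    elif tie_break == "conservative":
        n_le = int((finite_null <= observed + 1e-9).sum())
    else:
        n_lt = int((finite_null < observed - 1e-9).sum())
        n_tie = int((np.abs(finite_null - observed) <= 1e-9).sum())
        n_le = n_lt + int(rng.integers(0, n_tie + 1))
    empirical_p = (1 + n_le) / (n_perm + 1)
    return ProximityResult(
        drug=drug,
        tissue=tissue,
        deg_set_kind=deg_set_kind,
        source_db=source_db,
        observed_dist=observed,
        null_dists=null,
        empirical_p=empirical_p,
        n_deg_in_network=len(d),
        n_targets_in_network=len(t),
    )


# ---------------------------------------------------------------------------
# the six-combination screen and consensus rule
# ---------------------------------------------------------------------------


def run_proximity_screen(
    net: SignalingNetwork,
    deg_sets_by_tissue: Mapping[str, Mapping[str, set] | object],
    target_sets: Sequence[DrugTargetSet],
    n_perm: int = 1000,
    seed: int = 0,
    fdr_alpha: float = 0.05,
    mode: str = "undirected",
    degree_matched_null: bool = False,
    drop_unreachable: bool = False,
) -> tuple[list[ProximityResult], list[ConsensusCall]]:
    """Run all (drug, tissue, DEG-kind, source) proximity tests.

    FDR is Benjamini-Hochberg across drugs within each (tissue, DEG-kind,
    source) stratum. A (drug, tissue) pair is retained iff at least one
    DEG kind is significant (FDR < ``fdr_alpha``) in *every* source.
    """
    sources = sorted({ts.source_db for ts in target_sets})
    if not sources:
        raise ConfigurationError("target_sets: empty")
    for s in sources:
        if not any(ts.source_db == s for ts in target_sets):
            raise ConfigurationError(f"source {s!r}: no drugs")

    # normalise DEG input: accept DEGTable-like (gene_sets()) or plain dicts
    kinds_by_tissue: dict[str, dict[str, set[str]]] = {}
    for tissue, val in deg_sets_by_tissue.items():
        if hasattr(val, "gene_sets"):
            kinds_by_tissue[tissue] = val.gene_sets()
        else:
            kinds_by_tissue[tissue] = {k: set(val[k]) for k in val}

    node_set = set(net.nodes)
    results: list[ProximityResult] = []
    combos = []
    for tissue in sorted(kinds_by_tissue):
        for kind in DEG_KINDS:
            degs = {g.upper() for g in kinds_by_tissue[tissue].get(kind, set())}
            if not (degs & node_set):
                warnings.warn(
                    f"skipping tissue={tissue} kind={kind}: no DEGs in network",
                    stacklevel=2,
                )
                continue
            for ts in sorted(target_sets, key=lambda x: (x.source_db, x.drug)):
                if not (ts.targets & node_set):
                    continue
                combos.append((tissue, kind, ts, degs))
    if not combos:
        raise ConfigurationError("no runnable (tissue, kind, drug) combination")

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(combos))
    for (tissue, kind, ts, degs), child in zip(combos, children):
        res = proximity_permutation_test(
            net,
            degs,
            ts.targets,
            n_perm=n_perm,
            seed=np.random.default_rng(child),
            mode=mode,
            degree_matched_null=degree_matched_null,
            drop_unreachable=drop_unreachable,
            drug=ts.drug,
            tissue=tissue,
            deg_set_kind=kind,
            source_db=ts.source_db,
        )
        results.append(res)

    # BH across drugs within each (tissue, kind, source)
    strata: dict[tuple[str, str, str], list[ProximityResult]] = {}
    for r in results:
        strata.setdefault((r.tissue, r.deg_set_kind, r.source_db), []).append(r)
    for group in strata.values():
        pvals = np.array([r.empirical_p for r in group])
        _, fdrs, _, _ = multipletests(pvals, method="fdr_bh")
        for r, f in zip(group, fdrs):
            r.fdr = float(f)

    return results, consensus_calls(results, sources, fdr_alpha)


def consensus_calls(
    results: Sequence[ProximityResult],
    sources: Sequence[str],
    fdr_alpha: float = 0.05,
) -> list[ConsensusCall]:
    """Apply the consensus rule: retained iff >=1 significant DEG kind per source."""
    support: dict[tuple[str, str], dict[str, list[str]]] = {}
    for r in results:
        key = (r.drug, r.tissue)
        support.setdefault(key, {s: [] for s in sources})
        if r.fdr < fdr_alpha:
            support[key][r.source_db].append(r.deg_set_kind)
    return [
        ConsensusCall(
            drug=drug,
            tissue=tissue,
            supporting=sup,
            retained=all(len(sup[s]) > 0 for s in sources),
        )
        for (drug, tissue), sup in sorted(support.items())
    ]


def load_network(path: str | Path) -> SignalingNetwork:
    """Load an edge-list TSV or GraphML network file."""
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ParseError(f"{path}: missing or empty network file")
    if path.suffix.lower() in (".graphml", ".xml"):
        return SignalingNetwork.from_graphml(path)
    if path.suffix.lower() in (".tsv", ".txt", ".csv", ".edges"):
        return SignalingNetwork.from_edgelist_tsv(path)
    raise ParseError(f"{path}: unknown network format {path.suffix!r}")


def proximity_results_frame(results: Sequence[ProximityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "drug": r.drug,
                "tissue": r.tissue,
                "deg_kind": r.deg_set_kind,
                "source": r.source_db,
                "observed_dist": r.observed_dist,
                "p": r.empirical_p,
                "fdr": r.fdr,
                "n_deg_in_net": r.n_deg_in_network,
                "n_targets_in_net": r.n_targets_in_network,
            }
            for r in results
        ]
    )


def consensus_frame(calls: Sequence[ConsensusCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "drug": c.drug,
                "tissue": c.tissue,
                "retained": c.retained,
                **{
                    f"kinds_{s}": ",".join(sorted(k))
                    for s, k in sorted(c.supporting.items())
                },
            }
            for c in calls
        ]
    )
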