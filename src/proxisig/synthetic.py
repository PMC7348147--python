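"""Seeded generators for every pipeline input, with known planted structure.

Counts are negative-binomial (variance = mu + phi * mu^2) around log-normal
gene baselines; per-tissue DEGs are shifted by +-lfc_magnitude in the treated
group only. The network is a seeded preferential-attachment graph with edges
directed by node-index order and 10% reciprocated. Reference signatures are
rank-blended with noise to hit a requested Spearman correlation with the
treatment signature, verified before emission.

One global integer seed drives independent per-component generators, so each
component is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats as st

from proxisig.errors import ConfigurationError, SimulationError
from proxisig.expression import CountMatrix
from proxisig.network import DrugTargetSet, SignalingNetwork
from proxisig.signatures import Signature

_COMPONENT_KEYS = {"counts": 1, "network": 2, "drugs": 3, "signatures": 4}


@dataclass
class SimulationConfig:
    """All knobs for the synthetic inputs; same seed implies identical output."""

    n_tissues: int = 4
    n_genes: int = 2000
    n_replicates: int = 3
    deg_fraction: float = 0.05
    lfc_magnitude: float = 2.0
    nb_dispersion: float = 0.05
    libsize_range: tuple[float, float] = (5e5, 1.5e6)
    network_nodes: int = 300
    network_attach_param: int = 3
    n_drugs: int = 10
    targets_per_drug: int = 8
    planted_proximity_drugs: list[tuple[str, int]] = field(default_factory=list)
    n_reference_signatures: int = 20
    planted_correlations: list[tuple[str, str, float]] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_tissues",
            "n_genes",
            "n_replicates",
            "network_nodes",
            "network_attach_param",
            "n_drugs",
            "targets_per_drug",
            "n_reference_signatures",
        ):
            if int(getattr(self, name)) <= 0:
                raise ConfigurationError(f"{name}: must be positive")
        if not 0 <= self.deg_fraction < 1:
            raise ConfigurationError("deg_fraction: must be in [0, 1)")
        if self.lfc_magnitude < 0:
            raise ConfigurationError("lfc_magnitude: must be >= 0")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion: must be >= 0")
        lo, hi = self.libsize_range
        if not (0 < lo <= hi):
            raise ConfigurationError("libsize_range: need 0 < low <= high")
        if self.network_nodes > self.n_genes:
            raise ConfigurationError("network_nodes: cannot exceed n_genes")
        if self.network_attach_param >= self.network_nodes:
            raise ConfigurationError(
                "network_attach_param: must be below network_nodes"
            )
        if self.targets_per_drug >= self.network_nodes:
            raise ConfigurationError("targets_per_drug: must be below network_nodes")
        for sig_id, _topic, rho in self.planted_correlations:
            if not -1.0 <= rho <= 1.0:
                raise ConfigurationError(
                    f"planted_correlations: target SCC {rho} for {sig_id!r} "
                    f"outside [-1, 1]"
                )
        for drug, hops in self.planted_proximity_drugs:
            if hops < 0:
                raise ConfigurationError(
                    f"planted_proximity_drugs: negative hop distance for {drug!r}"
                )

    def rng(self, component: str) -> np.random.Generator:
        """Independent, reproducible generator for one pipeline component."""
        return np.random.default_rng(
            np.random.SeedSequence(
                entropy=int(self.seed), spawn_key=(_COMPONENT_KEYS[component],)
            )
        )

    def gene_names(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.n_genes)]

    def tissue_names(self) -> list[str]:
        return [f"tissue{i + 1:02d}" for i in range(self.n_tissues)]


@dataclass
class GroundTruth:
    """What was planted, for downstream acceptance checks."""

    planted_deg_sets: dict[str, tuple[set[str], set[str]]]  # tissue -> (up, down)
    planted_signature_scc: dict[str, float] = field(default_factory=dict)
    planted_proximal_drugs: list[str] = field(default_factory=list)

    def validate_against(self, cm: CountMatrix) -> None:
        genes = set(cm.genes)
        for tissue, (up, down) in self.planted_deg_sets.items():
            if up & down:
                raise SimulationError(f"{tissue}: planted up/down sets overlap")
            if not (up | down) <= genes:
                raise SimulationError(f"{tissue}: planted gene outside count matrix")

    def to_dict(self) -> dict:
        return {
            "planted_deg_sets": {
                t: {"up": sorted(u), "down": sorted(d)}
                for t, (u, d) in self.planted_deg_sets.items()
            },
            "planted_signature_scc": self.planted_signature_scc,
            "planted_proximal_drugs": list(self.planted_proximal_drugs),
        }


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


def _nb_draw(
    rng: np.random.Generator, mu: np.ndarray, phi: float
) -> np.ndarray:
    """NB with variance mu + phi*mu^2 (Poisson when phi == 0)."""
    if phi <= 0:
        return rng.poisson(mu)
    r = 1.0 / phi
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def simulate_counts(cfg: SimulationConfig) -> tuple[CountMatrix, GroundTruth]:
    """Simulate the multi-tissue count matrix with planted per-tissue DEGs."""
    cfg.validate()
    rng = cfg.rng("counts")
    genes = cfg.gene_names()
    tissues = cfg.tissue_names()

    baseline = rng.lognormal(mean=4.0, sigma=1.0, size=cfg.n_genes)
    # mild tissue-specific expression profile so tissues are separable
    tissue_effect = rng.lognormal(mean=0.0, sigma=0.4, size=(cfg.n_tissues, cfg.n_genes))
    gene_lengths = rng.integers(500, 5001, size=cfg.n_genes)

    n_deg = int(round(cfg.deg_fraction * cfg.n_genes))
    planted: dict[str, tuple[set[str], set[str]]] = {}
    fold = 2.0 ** cfg.lfc_magnitude

    columns = {}
    ann_rows = []
    for ti, tissue in enumerate(tissues):
        mu_tissue = baseline * tissue_effect[ti]
        chosen = rng.choice(cfg.n_genes, size=n_deg, replace=False)
        up_idx = chosen[: n_deg // 2]
        down_idx = chosen[n_deg // 2 :]
        planted[tissue] = (
            {genes[i] for i in up_idx},
            {genes[i] for i in down_idx},
        )
        shift = np.ones(cfg.n_genes)
        shift[up_idx] = fold
        shift[down_idx] = 1.0 / fold
        for group in ("treated", "control"):
            mu_group = mu_tissue * (shift if group == "treated" else 1.0)
            for rep in range(1, cfg.n_replicates + 1):
                lo, hi = cfg.libsize_range
                libsize = np.exp(rng.uniform(np.log(lo), np.log(hi)))
                scale = libsize / mu_group.sum()
                sample = f"{tissue}_{group}_r{rep}"
                columns[sample] = _nb_draw(rng, mu_group * scale, cfg.nb_dispersion)
                ann_rows.append(
                    {"sample": sample, "tissue": tissue, "group": group,
                     "replicate": rep}
                )

    counts = pd.DataFrame(columns, index=pd.Index(genes, name="gene"))
    annotations = pd.DataFrame(ann_rows).set_index("sample")
    cm = CountMatrix(
        counts=counts,
        annotations=annotations,
        gene_lengths=pd.Series(gene_lengths, index=genes, name="length"),
    )
    truth = GroundTruth(planted_deg_sets=planted)
    truth.validate_against(cm)
    return cm, truth


# ---------------------------------------------------------------------------
# network and drugs
# ---------------------------------------------------------------------------


def _build_scale_free(cfg: SimulationConfig, rng: np.random.Generator) -> SignalingNetwork:
    seed_int = int(rng.integers(0, 2 ** 31 - 1))
    ba = nx.barabasi_albert_graph(cfg.network_nodes, cfg.network_attach_param, seed=seed_int)
    genes = cfg.gene_names()
    edges = []
    und = []
    for u, v in sorted(ba.edges()):
        lo, hi = (u, v) if u < v else (v, u)
        edges.append((genes[lo], genes[hi], True))
        und.append((genes[lo], genes[hi]))
    # reciprocate 10% of edges
    n_recip = int(round(0.10 * len(und)))
    if n_recip:
        pick = rng.choice(len(und), size=n_recip, replace=False)
        for i in pick:
            a, b = und[i]
            edges.append((b, a, True))
    return SignalingNetwork(edges)


def simulate_network_and_drugs(
    cfg: SimulationConfig, truth: GroundTruth
) -> tuple[SignalingNetwork, list[DrugTargetSet]]:
    """Scale-free network plus two-source drug target sets.

    Planted drugs get targets chosen to *cover* the first tissue's in-network
    DEG set: targets are drawn within the stated hop distance (undirected) of
    DEG nodes, cycling through distinct DEGs so every DEG has a nearby target.
    Remaining drugs get uniformly random targets; both sources are planted
    identically for planted drugs and drawn independently otherwise.
    """
    cfg.validate()
    rng = cfg.rng("drugs")
    net = _build_scale_free(cfg, cfg.rng("network"))
    nodes = net.nodes
    node_set = set(nodes)

    if not truth.planted_deg_sets:
        raise SimulationError("ground truth has no planted DEG sets to plant near")
    first_tissue = sorted(truth.planted_deg_sets)[0]
    up, down = truth.planted_deg_sets[first_tissue]
    deg_nodes = sorted((up | down) & node_set)

    und = net.graph.to_undirected(as_view=True)
    drug_names = [f"drug{i + 1:02d}" for i in range(cfg.n_drugs)]
    planted_map = dict(cfg.planted_proximity_drugs)
    unknown = set(planted_map) - set(drug_names)
    if unknown:
        raise ConfigurationError(
            f"planted_proximity_drugs: unknown drugs {sorted(unknown)}"
        )

    sources = ("dbA", "dbB")
    target_sets: list[DrugTargetSet] = []
    for drug in drug_names:
        if drug in planted_map:
            hops = planted_map[drug]
            if not deg_nodes:
                raise SimulationError(
                    f"{drug}: no in-network DEGs in tissue {first_tissue!r}"
                )
            ball: dict[str, list[str]] = {}
            for d in deg_nodes:
                reach = nx.single_source_shortest_path_length(und, d, cutoff=hops)
                ball[d] = sorted(reach)
                if not ball[d]:
                    raise SimulationError(
                        f"{drug}: hop distance {hops} unreachable from {d}"
                    )
            order = list(rng.permutation(deg_nodes))
            targets: set[str] = set()
            i = 0
            guard = 0
            while len(targets) < cfg.targets_per_drug:
                d = order[i % len(order)]
                cand = ball[d]
                targets.add(cand[int(rng.integers(len(cand)))])
                i += 1
                guard += 1
                if guard > 50 * cfg.targets_per_drug:
                    raise SimulationError(
                        f"{drug}: cannot collect {cfg.targets_per_drug} distinct "
                        f"targets within {hops} hops"
                    )
            for src in sources:
                target_sets.append(
                    DrugTargetSet(drug=drug, targets=frozenset(targets), source_db=src)
                )
        else:
            for src in sources:
                pick = rng.choice(len(nodes), size=cfg.targets_per_drug, replace=False)
                target_sets.append(
                    DrugTargetSet(
                        drug=drug,
                        targets=frozenset(nodes[i] for i in pick),
                        source_db=src,
                    )
                )
    truth.planted_proximal_drugs = sorted(planted_map)
    return net, target_sets


# ---------------------------------------------------------------------------
# reference signatures
# ---------------------------------------------------------------------------


def _blend_to_target_scc(
    query: np.ndarray,
    rho_target: float,
    rng: np.random.Generator,
    tol: float = 0.02,
    max_iter: int = 50,
) -> np.ndarray:
    """Rank-blend noise onto the query to hit a target Spearman correlation."""
    n = len(query)
    z = st.zscore(st.rankdata(query))
    noise = rng.standard_normal(n)
    noise = st.zscore(st.rankdata(noise))  # decorrelated rank scores
    lo, hi = -1.0, 1.0

    def measured(w: float) -> tuple[float, np.ndarray]:
        cand = w * z + np.sqrt(max(1.0 - w * w, 0.0)) * noise
        rho = st.spearmanr(query, cand).statistic
        return float(rho), cand

    best_w, best_err, best_cand = 0.0, np.inf, noise
    w = rho_target
    for _ in range(max_iter):
        rho, cand = measured(w)
        err = abs(rho - rho_target)
        if err < best_err:
            best_w, best_err, best_cand = w, err, cand
        if err <= tol:
            return cand
        if rho < rho_target:
            lo = w
        else:
            hi = w
        w = (lo + hi) / 2.0
    return best_cand


def simulate_reference_signatures(
    cfg: SimulationConfig, treatment_sig: Signature
) -> list[Signature]:
    """Reference compendium with planted Spearman correlations to the query.

    Planted signatures achieve their target SCC within +-0.05 (verified by
    direct computation before emission); |target| = 1 is realised as an exact
    monotone transform (negated for -1). Unplanted signatures are independent
    permutations of the query values.
    """
    cfg.validate()
    if len(treatment_sig) == 0:
        raise ConfigurationError("treatment_sig: empty signature")
    rng = cfg.rng("signatures")
    q = treatment_sig.values.values.astype(float)
    genes = treatment_sig.values.index

    planted = {sig_id: (topic, rho) for sig_id, topic, rho in cfg.planted_correlations}
    out: list[Signature] = []
    for sig_id, (topic, rho) in planted.items():
        if abs(rho) >= 1.0 - 1e-12:
            vals = (2.0 * q + 1.0) * np.sign(rho)
        else:
            vals = _blend_to_target_scc(q, rho, rng)
        achieved = float(st.spearmanr(q, vals).statistic)
        if abs(achieved - rho) > 0.05:
            raise SimulationError(
                f"{sig_id}: achieved SCC {achieved:.3f} misses target {rho:.3f}"
            )
        out.append(
            Signature(
                id=sig_id,
                values=pd.Series(vals, index=genes),
                tissue=treatment_sig.tissue,
                topic=topic,
                polarity="neutral",
                platform="rnaseq",
            )
        )

    n_filler = max(cfg.n_reference_signatures - len(out), 0)
    polarities = ("beneficial", "deleterious", "neutral")
    for i in range(n_filler):
        vals = rng.permutation(q)
        out.append(
            Signature(
                id=f"ref{i + 1:03d}",
                values=pd.Series(vals, index=genes),
                tissue=treatment_sig.tissue,
                topic=f"topic{i % 5 + 1}",
                polarity=polarities[i % 3],
                platform="rnaseq",
            )
        )
    return out


# ---------------------------------------------------------------------------
# one-call generation of every pipeline input
# ---------------------------------------------------------------------------


def simulate_all(cfg: SimulationConfig, outdir) -> GroundTruth:
    """Generate and write every pipeline input plus the ground-truth manifest."""
    from pathlib import Path

    import numpy as np

    from proxisig import io as pio
    from proxisig.signatures import build_signature

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cm, truth = simulate_counts(cfg)
    pio.write_count_matrix(cm, outdir)
    net, targets = simulate_network_and_drugs(cfg, truth)
    pio.write_network(net, outdir)
    pio.write_drug_targets(targets, outdir / "drug_targets.tsv")

    # treatment signature of the first tissue anchors the reference compendium
    first = cfg.tissue_names()[0]
    ann = cm.annotations
    case = [s for s in cm.samples
            if ann.at[s, "tissue"] == first and ann.at[s, "group"] == "treated"]
    ctrl = [s for s in cm.samples
            if ann.at[s, "tissue"] == first and ann.at[s, "group"] == "control"]
    sig = build_signature(
        cm.counts.astype(float), "rnaseq", case, ctrl,
        sig_id=f"treatment_{first}", tissue=first,
    )
    refs = simulate_reference_signatures(cfg, sig)
    pio.write_signatures(refs, outdir / "reference_signatures.tsv")
    truth.planted_signature_scc = {
        sig_id: rho for sig_id, _topic, rho in cfg.planted_correlations
    }
    pio.write_json(truth.to_dict(), outdir / "ground_truth.json")
    return truth
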