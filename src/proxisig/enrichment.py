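"""Overlap-enrichment machinery and ortholog mapping.

Gene-set tests are one-sided hypergeometric over-representation; drug
class / side-effect / interaction tests are one-sided Fisher exact tests on
the 2x2 hit x label table, BH-adjusted by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from proxisig.errors import ConfigurationError, ParseError


@dataclass
class GeneSet:
    id: str
    genes: frozenset[str]
    category: str = ""
    description: str = ""


@dataclass
class GeneSetCollection:
    """Named gene sets over a declared universe."""

    sets: dict[str, GeneSet]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.sets) != len({s.id for s in self.sets.values()}):
            raise ConfigurationError("gene sets: duplicate ids")

    @classmethod
    def from_gmt(
        cls, path: str | Path, universe: Iterable[str] | None = None
    ) -> "GeneSetCollection":
        sets: dict[str, GeneSet] = {}
        all_genes: set[str] = set()
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ParseError(f"{path}:{lineno}: GMT line with <3 fields")
                sid, desc, genes = parts[0], parts[1], parts[2:]
                genes = [g for g in genes if g]
                if sid in sets:
                    raise ParseError(f"{path}:{lineno}: duplicate set id {sid!r}")
                sets[sid] = GeneSet(id=sid, genes=frozenset(genes), description=desc)
                all_genes.update(genes)
        uni = frozenset(universe) if universe is not None else frozenset(all_genes)
        return cls(sets=sets, universe=uni)

    def restricted(self) -> "GeneSetCollection":
        """Intersect every set with the universe."""
        return GeneSetCollection(
            sets={
                sid: GeneSet(
                    id=s.id,
                    genes=s.genes & self.universe,
                    category=s.category,
                    description=s.description,
                )
                for sid, s in self.sets.items()
            },
            universe=self.universe,
        )


@dataclass
class EnrichmentResult:
    feature: str
    k: int  # overlap
    K: int  # feature size
    n: int  # query size
    N: int  # universe size
    odds_ratio: float
    p_value: float
    p_adjusted: float = float("nan")


@dataclass
class DrugAnnotationTable:
    """Per-drug class labels, side-effect labels and a DDI flag."""

    classes: dict[str, frozenset[str]]
    side_effects: dict[str, frozenset[str]]
    interacts_with_query_drug: dict[str, bool]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DrugAnnotationTable":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        required = {"drug", "class", "side_effect", "ddi_flag"}
        missing = required - set(df.columns)
        if missing:
            raise ParseError(f"{path}: missing columns {sorted(missing)}")
        classes: dict[str, set[str]] = {}
        sides: dict[str, set[str]] = {}
        ddi: dict[str, bool] = {}
        for _, row in df.iterrows():
            d = row["drug"]
            classes.setdefault(d, set()).update(
                c for c in row["class"].split("|") if c
            )
            sides.setdefault(d, set()).update(
                c for c in row["side_effect"].split("|") if c
            )
            ddi[d] = ddi.get(d, False) or row["ddi_flag"].lower() in (
                "1",
                "true",
                "yes",
            )
        return cls(
            classes={d: frozenset(v) for d, v in classes.items()},
            side_effects={d: frozenset(v) for d, v in sides.items()},
            interacts_with_query_drug=ddi,
        )

    def labels_for(self, kind: str) -> dict[str, frozenset[str]]:
        if kind == "class":
            return self.classes
        if kind == "side_effect":
            return self.side_effects
        raise ConfigurationError(f"feature_kind: unknown {kind!r}")


# ---------------------------------------------------------------------------
# ortholog mapping
# ---------------------------------------------------------------------------


@dataclass
class OrthologReport:
    n_input: int
    n_mapped_input: int
    n_output: int
    unmapped: list[str]


def map_orthologs(
    genes: Iterable[str], table: pd.DataFrame | str | Path
) -> tuple[set[str], OrthologReport]:
    """Map gene symbols through a two-column (mouse, human) ortholog table.

    One-to-many mappings are expanded; many-to-one outputs deduplicated;
    unmapped inputs are reported, never silently dropped.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t", dtype=str)
    cols = {c.lower(): c for c in table.columns}
    if "mouse" not in cols or "human" not in cols:
        raise ConfigurationError("ortholog table: needs columns 'mouse' and 'human'")
    if len(table) == 0:
        raise ConfigurationError("ortholog table: empty")
    mapping: dict[str, set[str]] = {}
    for _, row in table.iterrows():
        mapping.setdefault(str(row[cols["mouse"]]), set()).add(str(row[cols["human"]]))
    genes = list(genes)
    out: set[str] = set()
    unmapped: list[str] = []
    for g in genes:
        if g in mapping:
            out |= mapping[g]
        else:
            unmapped.append(g)
    return out, OrthologReport(
        n_input=len(genes),
        n_mapped_input=len(genes) - len(unmapped),
        n_output=len(out),
        unmapped=sorted(unmapped),
    )


# ---------------------------------------------------------------------------
# enrichment tests
# ---------------------------------------------------------------------------


def _adjust(pvals: Sequence[float], method: str) -> np.ndarray:
    if not len(pvals):
        return np.array([])
    if method == "bh":
        return multipletests(pvals, method="fdr_bh")[1]
    if method == "bonferroni":
        return np.minimum(np.asarray(pvals) * len(pvals), 1.0)
    raise ConfigurationError(f"correction: unknown {method!r}")


def _odds_ratio(k: int, K: int, n: int, N: int) -> float:
    a, b, c, d = k, n - k, K - k, N - K - (n - k)
    if b * c == 0:
        if a * d == 0:
            return 1.0  # degenerate table (a full margin); association undefined
        return float("inf")
    if a * d == 0:
        return 0.0
    return (a * d) / (b * c)


def gene_set_enrichment(
    query: Iterable[str],
    collection: GeneSetCollection,
    correction: str = "bh",
) -> list[EnrichmentResult]:
    """One-sided hypergeometric over-representation of the query in each set."""
    query = set(query)
    outside = query - set(collection.universe)
    if outside:
        raise ConfigurationError(
            f"query genes outside universe: {sorted(outside)[:5]}"
            + ("..." if len(outside) > 5 else "")
        )
    restricted = collection.restricted()
    N = len(restricted.universe)
    n = len(query)
    results = []
    for sid, gs in sorted(restricted.sets.items()):
        K = len(gs.genes)
        k = len(query & gs.genes)
        p = float(st.hypergeom.sf(k - 1, N, K, n))
        results.append(
            EnrichmentResult(
                feature=sid,
                k=k,
                K=K,
                n=n,
                N=N,
                odds_ratio=_odds_ratio(k, K, n, N),
                p_value=min(p, 1.0),
            )
        )
    adj = _adjust([r.p_value for r in results], correction)
    for r, a in zip(results, adj):
        r.p_adjusted = float(a)
    return sorted(results, key=lambda r: (r.p_value, r.feature))


def drug_feature_enrichment(
    hit_drugs: Iterable[str],
    all_drugs: Iterable[str],
    annotations: DrugAnnotationTable,
    feature_kind: str = "class",
    correction: str = "bh",
) -> list[EnrichmentResult]:
    """Fisher exact enrichment of drug features among hit drugs.

    ``feature_kind`` is ``class``, ``side_effect`` or ``interaction``; the
    interaction kind tests the single boolean DDI flag.
    """
    hits = set(hit_drugs)
    alld = set(all_drugs)
    if not hits:
        raise ConfigurationError("hit_drugs: empty")
    if not hits <= alld:
        raise ConfigurationError("hit_drugs: not a subset of all_drugs")

    if feature_kind == "interaction":
        flagged = {
            d for d in alld if annotations.interacts_with_query_drug.get(d, False)
        }
        features = {"ddi": flagged}
    else:
        label_map = annotations.labels_for(feature_kind)
        features = {}
        for d in alld:
            for lab in label_map.get(d, frozenset()):
                features.setdefault(lab, set()).add(d)

    N = len(alld)
    n = len(hits)
    results = []
    for lab, carriers in sorted(features.items()):
        K = len(carriers)
        k = len(hits & carriers)
        table = [[k, n - k], [K - k, N - K - (n - k)]]
        _, p = st.fisher_exact(table, alternative="greater")
        results.append(
            EnrichmentResult(
                feature=lab,
                k=k,
                K=K,
                n=n,
                N=N,
                odds_ratio=_odds_ratio(k, K, n, N),
                p_value=float(p),
            )
        )
    adj = _adjust([r.p_value for r in results], correction)
    for r, a in zip(results, adj):
        r.p_adjusted = float(a)
    return sorted(results, key=lambda r: (r.p_value, r.feature))


def results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature": r.feature,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "odds_ratio": r.odds_ratio,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
            }
            for r in results
        ]
    )
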