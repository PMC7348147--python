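"""Log2 fold-change signatures and Spearman comparison against a compendium.

A signature is an ordered map gene -> log2 fold change with a tissue, a topic
label, a polarity tag and the platform it was derived from. Signatures are
compared by Spearman correlation on shared genes only, with Bonferroni
correction over the testable references.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

from proxisig.errors import ConfigurationError

PLATFORMS = ("two_colour_paired", "two_colour_reference", "one_colour", "rnaseq")
POLARITIES = ("beneficial", "deleterious", "neutral")

MIN_SHARED = 3  # fewer shared genes than this -> untestable pair


@dataclass
class Signature:
    """Per-gene log2 fold changes for one perturbation."""

    id: str
    values: pd.Series  # index gene, float log2fc
    tissue: str = ""
    topic: str = ""
    polarity: str = "neutral"
    platform: str = "rnaseq"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ConfigurationError(f"signature {self.id}: duplicate gene keys")
        if not np.isfinite(self.values.values).all():
            raise ConfigurationError(f"signature {self.id}: non-finite values")
        if self.polarity not in POLARITIES:
            raise ConfigurationError(
                f"signature {self.id}: unknown polarity {self.polarity!r}"
            )
        if self.platform not in PLATFORMS:
            raise ConfigurationError(
                f"signature {self.id}: unknown platform {self.platform!r}"
            )

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class SignatureCorrelation:
    query_id: str
    reference_id: str
    scc: float
    n_shared: int
    p_value: float
    p_adjusted: float
    significant: bool
    testable: bool = True


# ---------------------------------------------------------------------------
# signature construction
# ---------------------------------------------------------------------------


def build_signature(
    samples: pd.DataFrame,
    design: str,
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    sig_id: str = "signature",
    tissue: str = "",
    topic: str = "",
    polarity: str = "neutral",
    log_transformed: bool = False,
) -> Signature:
    """Build a log2 fold-change signature from an expression table.

    Paired two-colour designs average per-pair log2 signal ratios; all other
    designs (one-colour, two-colour with universal reference, RNA-seq) take
    mean(log2 case) - mean(log2 control). Values are log2-transformed first
    unless ``log_transformed``; RNA-seq values get a +1 pseudocount before
    the transform.
    """
    if design not in PLATFORMS:
        raise ConfigurationError(f"design: unknown platform {design!r}")
    if not len(case_ids) or not len(control_ids):
        raise ConfigurationError("case_ids/control_ids: must be nonempty")
    for cid in list(case_ids) + list(control_ids):
        if cid not in samples.columns:
            raise ConfigurationError(f"sample {cid!r} not in expression table")

    def to_log2(df: pd.DataFrame) -> pd.DataFrame:
        if log_transformed:
            return df.astype(float)
        x = df.astype(float)
        if design == "rnaseq":
            x = x + 1.0
        bad = x.le(0).any(axis=1)
        if bad.any():
            offender = x.index[bad][0]
            raise ConfigurationError(
                f"non-positive intensity for gene {offender!r} on platform "
                f"requiring log transform"
            )
        return np.log2(x)

    if design == "two_colour_paired":
        if len(case_ids) != len(control_ids):
            raise ConfigurationError(
                "paired design: case and control lists must have equal length"
            )
        case = to_log2(samples[list(case_ids)])
        ctrl = to_log2(samples[list(control_ids)])
        lfc = (case.values - ctrl.values).mean(axis=1)
    else:
        case = to_log2(samples[list(case_ids)])
        ctrl = to_log2(samples[list(control_ids)])
        lfc = case.values.mean(axis=1) - ctrl.values.mean(axis=1)

    values = pd.Series(lfc, index=samples.index, name=sig_id)
    return Signature(
        id=sig_id,
        values=values,
        tissue=tissue,
        topic=topic,
        polarity=polarity,
        platform=design,
    )


# ---------------------------------------------------------------------------
# Spearman machinery
# ---------------------------------------------------------------------------


def _exact_spearman_pvalue(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation p for small n (< 10 shared genes)."""
    n = len(x)
    rx = st.rankdata(x)
    ry = st.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    count = 0
    total = 0
    target = abs(np.mean(rx * ry))
    for perm in itertools.permutations(range(n)):
        r = abs(np.mean(rx[list(perm)] * ry))
        if r >= target - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman(
    a: pd.Series, b: pd.Series
) -> tuple[float, int, float]:
    """SCC, shared-gene count and two-sided p on the genes shared by a and b.

    Average ranks for ties; t approximation for n >= 10, exact permutation
    below that.
    """
    shared = a.index.intersection(b.index)
    n = len(shared)
    if n < MIN_SHARED:
        return float("nan"), n, float("nan")
    x = a.loc[shared].values.astype(float)
    y = b.loc[shared].values.astype(float)
    if np.ptp(st.rankdata(x)) == 0 or np.ptp(st.rankdata(y)) == 0:
        return float("nan"), n, float("nan")
    rho, p = st.spearmanr(x, y)
    rho = float(rho)
    if n < 10:
        p = _exact_spearman_pvalue(x, y, rho)
    elif abs(rho) >= 1.0 - 1e-12:
        p = 0.0
    return rho, n, float(p)


def correlate_signatures(
    query: Signature,
    refs: Sequence[Signature],
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> list[SignatureCorrelation]:
    """Correlate the query against each reference on shared genes.

    References sharing fewer than 3 genes are reported untestable and are
    excluded from the correction count; p_adjusted = min(1, p * n_testable).
    """
    if not refs:
        raise ConfigurationError("refs: must be nonempty")
    if correction != "bonferroni":
        raise ConfigurationError(f"correction: unknown {correction!r}")
    raw = []
    for ref in refs:
        rho, n, p = spearman(query.values, ref.values)
        raw.append((ref, rho, n, p))
    n_tests = sum(1 for _, rho, n, _ in raw if n >= MIN_SHARED and np.isfinite(rho))
    out = []
    for ref, rho, n, p in raw:
        testable = n >= MIN_SHARED and np.isfinite(rho)
        if testable:
            p_adj = min(1.0, p * n_tests)
            out.append(
                SignatureCorrelation(
                    query_id=query.id,
                    reference_id=ref.id,
                    scc=rho,
                    n_shared=n,
                    p_value=p,
                    p_adjusted=p_adj,
                    significant=p_adj < alpha,
                    testable=True,
                )
            )
        else:
            out.append(
                SignatureCorrelation(
                    query_id=query.id,
                    reference_id=ref.id,
                    scc=float("nan"),
                    n_shared=n,
                    p_value=float("nan"),
                    p_adjusted=float("nan"),
                    significant=False,
                    testable=False,
                )
            )
    return out


def correlate_with_drug_signatures(
    query: Signature,
    drug_sigs: Sequence[Signature],
    alpha: float = 0.05,
) -> list[SignatureCorrelation]:
    """Tissue-matched signature correlation with Bonferroni over matched tests."""
    if not query.tissue:
        raise ConfigurationError("query: tissue label required")
    matched = [s for s in drug_sigs if s.tissue == query.tissue]
    if not matched:
        import warnings

        warnings.warn(
            f"no drug signature matches query tissue {query.tissue!r}",
            stacklevel=2,
        )
        return []
    return correlate_signatures(query, matched, alpha=alpha)


# ---------------------------------------------------------------------------
# redundancy pruning
# ---------------------------------------------------------------------------


def prune_redundant(
    refs: Sequence[Signature], scc_cutoff: float = 0.5
) -> list[Signature]:
    """Remove redundant same-topic signatures (pairwise SCC > cutoff).

    Within each topic, signatures whose pairwise SCC exceeds the cutoff are
    linked; one representative per connected component survives — the one
    with the most genes, ties broken by lexicographic id. Cross-topic pairs
    are never pruned.
    """
    import networkx as nx

    by_topic: dict[str, list[Signature]] = {}
    for s in refs:
        by_topic.setdefault(s.topic, []).append(s)
    survivors: list[Signature] = []
    for topic, sigs in by_topic.items():
        g = nx.Graph()
        g.add_nodes_from(s.id for s in sigs)
        by_id = {s.id: s for s in sigs}
        for s1, s2 in itertools.combinations(sigs, 2):
            rho, n, _ = spearman(s1.values, s2.values)
            if n >= MIN_SHARED and np.isfinite(rho) and rho > scc_cutoff:
                g.add_edge(s1.id, s2.id)
        for comp in nx.connected_components(g):
            # most genes wins; among ties the lexicographically smallest id
            best = sorted(comp, key=lambda i: (-len(by_id[i]), i))[0]
            survivors.append(by_id[best])
    return sorted(survivors, key=lambda s: s.id)


# ---------------------------------------------------------------------------
# polarity-aware summary
# ---------------------------------------------------------------------------


def polarity_summary(
    correlations: Sequence[SignatureCorrelation],
    refs: Sequence[Signature],
    alpha: float = 0.05,
) -> dict:
    """Counts of significant positive/negative correlations by reference polarity."""
    pol = {s.id: s.polarity for s in refs}
    out = {
        p: {"positive": 0, "negative": 0}
        for p in POLARITIES
    }
    for c in correlations:
        if not c.testable or not c.significant:
            continue
        side = "positive" if c.scc > 0 else "negative"
        out[pol.get(c.reference_id, "neutral")][side] += 1
    return out
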