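"""Evaluation statistics for annotated transcriptional modules.

Implements the module-level quality measures: hypergeometric enrichment of
an ATM's pooled genes+TFs against curated gene-set categories (GMT),
Mann–Whitney AUC of the ranked term list against the tokenized category
descriptions, precision of gene–TF membership against gold-standard sets
with a right-tailed Welch's t-test null built from random gene–TF sets,
Jaccard redundancy, per-run diversity coefficients, and the two functional
classification prediction procedures (guilt-by-association and term
mapping).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .atm import ATM
from .corpus import tokenize

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "EnrichmentResult",
    "read_gmt",
    "hypergeom_enrich",
    "enrich_atms",
    "term_auc",
    "atm_precision",
    "welch_right_tailed",
    "random_control_sets",
    "matched_control_sets",
    "jaccard",
    "diversity_coefficient",
    "gba_predictions",
    "term_mapping_predictions",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset[str]


@dataclass
class GeneSetCollection:
    """Curated categories restricted to an identifier universe."""

    sets: dict[str, GeneSet]
    universe: frozenset[str]

    @classmethod
    def from_dict(
        cls, sets: dict[str, tuple[str, str, set[str]]], universe: set[str] | None = None
    ) -> "GeneSetCollection":
        if universe is None:
            universe = set().union(*(m for _, _, m in sets.values()))
        universe = frozenset(universe)
        kept: dict[str, GeneSet] = {}
        dropped = 0
        for cid, (name, desc, members) in sets.items():
            restricted = frozenset(members) & universe
            if restricted:
                kept[cid] = GeneSet(name, desc, restricted)
            else:
                dropped += 1
        if dropped:
            logger.info("dropped %d gene sets with no members in the universe", dropped)
        return cls(kept, universe)


def read_gmt(
    path: str | Path,
    universe: set[str] | None = None,
    descriptions: str | Path | None = None,
) -> GeneSetCollection:
    """GMT reader (id <TAB> description <TAB> members...).

    Member identifiers are upper-cased.  An optional two-column TSV maps
    set ids to free-text descriptions for the term-mapping procedure.
    """
    desc_map: dict[str, str] = {}
    if descriptions is not None:
        with open(descriptions) as fh:
            for line in fh:
                if line.strip():
                    cid, _, text = line.rstrip("\n").partition("\t")
                    desc_map[cid] = text
    raw: dict[str, tuple[str, str, set[str]]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not line.strip():
                continue
            cid, desc, members = fields[0], fields[1], {m.upper() for m in fields[2:] if m}
            raw[cid] = (cid, desc_map.get(cid, desc), members)
    return GeneSetCollection.from_dict(raw, universe)


@dataclass(frozen=True)
class EnrichmentResult:
    atm_id: int
    category_id: str
    overlap: int
    atm_size: int
    category_size: int
    universe_size: int
    p_value: float

    @property
    def enriched(self) -> bool:
        return self.p_value <= 0.05


def hypergeom_enrich(
    atm_members: set[str],
    category: set[str],
    universe: set[str],
    atm_id: int = -1,
    category_id: str = "",
) -> EnrichmentResult:
    """Upper-tail hypergeometric test P(X >= |atm ∩ category|).

    X ~ Hypergeom(N=|universe|, M=|category|, n=|atm|); the ATM's pooled
    genes and TFs are the draw.
    """
    if not atm_members:
        raise ValueError("empty ATM")
    if not universe:
        raise ValueError("empty universe")
    atm = set(atm_members) & set(universe)
    cat = set(category) & set(universe)
    x = len(atm & cat)
    N, M, n = len(universe), len(cat), len(atm)
    p = float(stats.hypergeom.sf(x - 1, N, M, n))
    return EnrichmentResult(atm_id, category_id, x, n, M, N, min(p, 1.0))


def enrich_atms(
    atms: list[ATM],
    collection: GeneSetCollection,
    alpha: float = 0.05,
    correction: str | None = None,
) -> list[EnrichmentResult]:
    """All (ATM, category) hypergeometric tests.

    Raw p-values by default; ``correction='bh'`` applies the
    Benjamini–Hochberg adjustment across all tests.
    """
    results = []
    for idx, atm in enumerate(atms):
        members = atm.members & collection.universe
        if not members:
            continue
        for cid, gs in collection.sets.items():
            results.append(
                hypergeom_enrich(members, gs.members, collection.universe, idx, cid)
            )
    if correction == "bh" and results:
        adjusted = stats.false_discovery_control([r.p_value for r in results])
        results = [
            EnrichmentResult(
                r.atm_id, r.category_id, r.overlap, r.atm_size,
                r.category_size, r.universe_size, float(p),
            )
            for r, p in zip(results, adjusted)
        ]
    elif correction not in (None, "bh"):
        raise ValueError(f"unknown correction {correction!r}")
    return results


def term_auc(ranked_terms: list[str], relevant: set[str]) -> float | None:
    """Mann–Whitney AUC of a ranked term list with `relevant` as positives.

    1 when every relevant term precedes every irrelevant one, 0 for the
    reverse, 0.5 in expectation for a random order.  Returns None (with a
    warning) when the list contains no positive or no negative terms.
    """
    if not ranked_terms:
        raise ValueError("empty ranking")
    y = np.array([t in relevant for t in ranked_terms], dtype=int)
    if y.all() or not y.any():
        warnings.warn("AUC undefined: ranking has no positives or no negatives", stacklevel=2)
        return None
    scores = -np.arange(len(ranked_terms), dtype=float)  # earlier rank = higher score
    return float(roc_auc_score(y, scores))


def atm_precision(atm_members: set[str], gold: set[str]) -> float:
    """|ATM ∩ gold| / |ATM| over pooled gene+TF identifiers."""
    if not atm_members:
        raise ValueError("empty ATM")
    return len(set(atm_members) & set(gold)) / len(set(atm_members))


def welch_right_tailed(sample1, sample2) -> tuple[float, float, float]:
    """Right-tailed two-sample Welch's t-test: (t, df, p).

    Tests mean(sample1) > mean(sample2) without assuming equal variances;
    df by Welch–Satterthwaite.  t = 0 gives p = 0.5.
    """
    a = np.asarray(sample1, dtype=float)
    b = np.asarray(sample2, dtype=float)
    if len(a) < 2 or len(b) < 2 or not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("each sample needs >= 2 finite values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("zero variance in both samples")
    res = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
    return float(res.statistic), float(res.df), float(res.pvalue)


def random_control_sets(
    gene_pool,
    tf_pool,
    n_genes: int = 8,
    n_tfs: int = 2,
    reps: int = 1000,
    seed: int | np.random.Generator = 0,
) -> list[set[str]]:
    """Random gene–TF sets (defaults: 8 genes + 2 TFs, 1000 reps).

    The defaults are the median module size; used as the enrichment /
    precision null.  Sampling is without replacement within a set.
    """
    genes = sorted(gene_pool)
    tfs = sorted(tf_pool)
    if len(genes) < n_genes or len(tfs) < n_tfs:
        raise ValueError("pool smaller than requested set size")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for _ in range(reps):
        picked = set(rng.choice(genes, size=n_genes, replace=False))
        picked |= set(rng.choice(tfs, size=n_tfs, replace=False))
        out.append(picked)
    return out


def matched_control_sets(
    atms: list[ATM],
    gene_pool,
    tf_pool,
    reps_per_atm: int = 200,
    seed: int = 0,
) -> list[set[str]]:
    """For each ATM, random sets matching its gene/TF counts (200 each)."""
    rng = np.random.default_rng(seed)
    out: list[set[str]] = []
    for atm in atms:
        out.extend(
            random_control_sets(
                gene_pool, tf_pool,
                n_genes=len(atm.genes), n_tfs=len(atm.tfs),
                reps=reps_per_atm, seed=rng,
            )
        )
    return out


def jaccard(set_a, set_b) -> float:
    """|A ∩ B| / |A ∪ B|; 1 for duplicates, 0 for disjoint sets."""
    a, b = set(set_a), set(set_b)
    if not a and not b:
        raise ValueError("jaccard undefined for two empty sets")
    return len(a & b) / len(a | b)


def diversity_coefficient(
    atms: list[ATM], tensor_totals: tuple[int, int, int]
) -> tuple[float, float, float] | None:
    """Per-run fraction of the tensor's entities covered by the k modules.

    ``tensor_totals`` is (n_terms, n_genes, n_tfs).  Defined only for runs
    with k >= 2; returns None otherwise.
    """
    if not atms or atms[0].k_of_run < 2:
        return None
    n_terms, n_genes, n_tfs = tensor_totals
    terms = set().union(*(set(a.term_labels) for a in atms))
    genes = set().union(*(set(a.gene_labels) for a in atms))
    tfs = set().union(*(set(a.tf_labels) for a in atms))
    return len(genes) / n_genes, len(tfs) / n_tfs, len(terms) / n_terms


@dataclass(frozen=True)
class Prediction:
    entity: str
    category_id: str
    supporting_atms: tuple[int, ...]


def gba_predictions(
    atms: list[ATM],
    enrichments: list[EnrichmentResult],
    annotations: dict[str, set[str]],
    alpha: float = 0.05,
) -> list[Prediction]:
    """Guilt-by-association assignments.

    For every (ATM, category) pair enriched at p <= alpha, each pooled
    member of the ATM not already annotated to that category becomes a
    candidate assignment; candidates are deduplicated across ATMs and carry
    the supporting ATM ids.
    """
    support: dict[tuple[str, str], set[int]] = {}
    for res in enrichments:
        if res.p_value > alpha:
            continue
        annotated = annotations.get(res.category_id, set())
        for entity in sorted(atms[res.atm_id].members - annotated):
            support.setdefault((entity, res.category_id), set()).add(res.atm_id)
    return [
        Prediction(entity, cid, tuple(sorted(ids)))
        for (entity, cid), ids in sorted(support.items())
    ]


def term_mapping_predictions(
    atm: ATM,
    collection: GeneSetCollection,
    enriched_category_ids: set[str],
    stoplist: frozenset[str] = frozenset(),
    min_overlap: int = 1,
) -> list[tuple[str, int]]:
    """Novel categories ranked by term overlap with their descriptions.

    Category names+descriptions are tokenized with the corpus tokenizer so
    the module's significant terms and the description tokens share one
    vocabulary; categories already enriched for this ATM are excluded.
    """
    atm_terms = set(atm.term_labels)
    scored = []
    for cid, gs in collection.sets.items():
        if cid in enriched_category_ids:
            continue
        toks = set(tokenize(f"{gs.name} {gs.description}", stoplist))
        overlap = len(atm_terms & toks)
        if overlap >= min_overlap:
            scored.append((cid, overlap))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored
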