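"""Annotated transcriptional modules (ATMs) from CP components.

Each rank-1 component yields one ATM: per mode (terms, genes, TFs) the
column scores are truncated to the top ``bound`` entities, the number of
significant entities is chosen by the normalized-entropy rule of Alter et
al., and the top-s entities are kept with their scores.  The default
bounds — 300 terms, 184 genes, 21 TFs — mirror the maxima observed across
curated KEGG pathways (and an abstract-length cap for terms).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .factorization import FactorModel

__all__ = [
    "ATM",
    "Bounds",
    "normalized_entropy",
    "significant_count",
    "extract_atms",
    "save_atms_json",
    "load_atms_json",
    "save_atms_tsv",
]

Ranked = list[tuple[str, float]]


@dataclass(frozen=True)
class Bounds:
    terms: int = 300
    genes: int = 184
    tfs: int = 21


@dataclass
class ATM:
    """One module: ranked significant terms, genes and TFs of a component."""

    component_index: int
    k_of_run: int
    weight: float  # the component's lambda
    terms: Ranked
    genes: Ranked
    tfs: Ranked
    degenerate: bool = False

    @property
    def gene_labels(self) -> list[str]:
        return [g for g, _ in self.genes]

    @property
    def tf_labels(self) -> list[str]:
        return [t for t, _ in self.tfs]

    @property
    def term_labels(self) -> list[str]:
        return [t for t, _ in self.terms]

    @property
    def members(self) -> set[str]:
        """Pooled gene + TF identifiers (the unit of the enrichment tests)."""
        return set(self.gene_labels) | set(self.tf_labels)


def normalized_entropy(scores) -> float:
    """Shannon entropy of the score distribution divided by log n.

    1 for a uniform list, 0 for a point mass; base-independent.  Requires
    n >= 2 entries with positive sum; 0·log 0 is taken as 0.
    """
    g = np.asarray(scores, dtype=float)
    if g.ndim != 1 or len(g) < 2:
        raise ValueError("need at least two scores")
    if np.any(g < 0):
        raise ValueError("scores must be non-negative")
    s = g.sum()
    if s <= 0:
        raise ValueError("degenerate list: all scores zero")
    p = g / s
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum() / math.log2(len(g)))


def significant_count(scores, rule: str = "scaled") -> int:
    """Number of dominant entries: s = max(1, |{p_i > E/n}|).

    ``rule='scaled'`` uses the threshold E/n (default); ``rule='inverse'``
    uses 1/(n·E), an alternative reading of the same entropy filter.
    """
    g = np.asarray(scores, dtype=float)
    E = normalized_entropy(g)
    n = len(g)
    p = g / g.sum()
    if rule == "scaled":
        thr = E / n
    elif rule == "inverse":
        thr = math.inf if E == 0 else 1.0 / (n * E)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return max(1, int(np.sum(p > thr)))


def _ranked_mode(
    column: np.ndarray, labels: tuple[str, ...], bound: int, rule: str
) -> tuple[Ranked, bool]:
    """Truncate to top-`bound`, apply the entropy rule, keep the top s."""
    order = sorted(range(len(column)), key=lambda a: (-column[a], labels[a]))
    top = order[: min(bound, len(order))]
    scores = column[top]
    if scores.sum() <= 0:
        # all-zero mode column: emit a single placeholder, flag degenerate
        return [(labels[top[0]], 0.0)], True
    if len(top) == 1:
        s = 1
    else:
        s = significant_count(scores, rule)
    kept = top[:s]
    return [(labels[a], float(column[a])) for a in kept], False


def extract_atms(
    model: FactorModel,
    bounds: Bounds = Bounds(),
    rule: str = "scaled",
) -> list[ATM]:
    """One ATM per component of a fitted CP model.

    Mode columns are ranked by score (ties broken lexicographically by
    label), truncated to the bound, and cut at the entropy-derived count s.
    Missing axis labels fall back to stringified indices.
    """
    labels = model.axis_labels
    if labels is None:
        labels = tuple(
            tuple(f"{prefix}{a}" for a in range(dim))
            for prefix, dim in zip(("term", "gene", "tf"), (model.A.shape[0], model.B.shape[0], model.C.shape[0]))
        )
    atms = []
    for r in range(model.rank):
        terms, d1 = _ranked_mode(model.A[:, r], labels[0], bounds.terms, rule)
        genes, d2 = _ranked_mode(model.B[:, r], labels[1], bounds.genes, rule)
        tfs, d3 = _ranked_mode(model.C[:, r], labels[2], bounds.tfs, rule)
        atms.append(
            ATM(
                component_index=r,
                k_of_run=model.rank,
                weight=float(model.lam[r]),
                terms=terms,
                genes=genes,
                tfs=tfs,
                degenerate=d1 or d2 or d3,
            )
        )
    return atms


# ---------------------------------------------------------------------------
# Serialization

def save_atms_json(atms: list[ATM], path: str | Path) -> None:
    recs = [
        {
            "component_index": a.component_index,
            "k_of_run": a.k_of_run,
            "weight": a.weight,
            "terms": a.terms,
            "genes": a.genes,
            "tfs": a.tfs,
            "degenerate": a.degenerate,
        }
        for a in atms
    ]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(recs, fh, indent=1)


def load_atms_json(path: str | Path) -> list[ATM]:
    with open(path) as fh:
        recs = json.load(fh)
    return [
        ATM(
            component_index=r["component_index"],
            k_of_run=r["k_of_run"],
            weight=r["weight"],
            terms=[(t, s) for t, s in r["terms"]],
            genes=[(t, s) for t, s in r["genes"]],
            tfs=[(t, s) for t, s in r["tfs"]],
            degenerate=r.get("degenerate", False),
        )
        for r in recs
    ]


def save_atms_tsv(atms: list[ATM], path: str | Path) -> None:
    """Flat table: run_k, atm_id, mode, rank, entity, score."""
    with open(path, "w") as fh:
        fh.write("run_k\tatm_id\tmode\trank\tentity\tscore\n")
        for a in atms:
            for mode, ranked in (("term", a.terms), ("gene", a.genes), ("tf", a.tfs)):
                for pos, (entity, score) in enumerate(ranked, 1):
                    fh.write(f"{a.k_of_run}\t{a.component_index}\t{mode}\t{pos}\t{entity}\t{score!r}\n")
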