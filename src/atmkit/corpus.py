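"""Gene–TF shared-citation document collection.

Builds the corpus that the term × gene × TF tensor is counted from: a
gene → PubMed-citation map (gene2pubmed style), a curated transcription
factor list, and per-citation title+abstract texts.  A document is formed
for every (gene, TF) pair that shares at least one citation, by
concatenating the titles and abstracts of the shared citations.  Citations
referring to too many genes (high-throughput surveys) are filtered out
before pairing.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

__all__ = [
    "CitationCorpus",
    "PairDocument",
    "Vocabulary",
    "filter_citations",
    "build_pair_documents",
    "tokenize",
    "count_terms",
    "read_gene2pubmed",
    "read_abstracts_jsonl",
    "read_id_list",
    "read_stoplist",
    "default_stoplist",
    "load_corpus",
]


@dataclass
class CitationCorpus:
    """Citation map, TF designation and abstract texts after filtering.

    An identifier present in ``tf_ids`` acts as a TF for tensor purposes;
    every other identifier with citations is a (non-TF) gene.  PMIDs in
    ``gene_to_pmids`` that have no abstract text are dropped by
    :meth:`validate` with a logged count.
    """

    gene_to_pmids: dict[str, set[int]]
    tf_ids: set[str]
    abstracts: dict[int, str]
    provenance: str = ""

    def validate(self) -> "CitationCorpus":
        """Enforce invariants in place; returns self for chaining."""
        known = set(self.abstracts)
        dropped = 0
        for gene in list(self.gene_to_pmids):
            pmids = self.gene_to_pmids[gene] & known
            dropped += len(self.gene_to_pmids[gene]) - len(pmids)
            if pmids:
                self.gene_to_pmids[gene] = pmids
            else:
                del self.gene_to_pmids[gene]
        if dropped:
            logger.info("dropped %d citation links without abstract text", dropped)
        return self

    @property
    def genes(self) -> list[str]:
        """Sorted non-TF gene identifiers with at least one citation."""
        return sorted(g for g in self.gene_to_pmids if g not in self.tf_ids)

    @property
    def tfs(self) -> list[str]:
        """Sorted TF identifiers with at least one citation."""
        return sorted(g for g in self.gene_to_pmids if g in self.tf_ids)


@dataclass(frozen=True)
class PairDocument:
    """One (gene, TF) pair and the concatenated text of its shared citations."""

    gene: str
    tf: str
    pmids: frozenset[int]
    text: str


@dataclass(frozen=True)
class Vocabulary:
    """Ordered term list with its inverse index map (lexicographic order)."""

    terms: tuple[str, ...]
    term_to_index: Mapping[str, int] = field(hash=False, compare=False, default=None)

    @classmethod
    def from_terms(cls, terms: Iterable[str]) -> "Vocabulary":
        ordered = tuple(sorted(set(terms)))
        return cls(ordered, {t: i for i, t in enumerate(ordered)})

    def __len__(self) -> int:
        return len(self.terms)


def filter_citations(
    raw_map: Mapping[str, set[int]], max_genes_per_pmid: int = 10
) -> dict[str, set[int]]:
    """Drop non-specific citations referenced by too many genes.

    A PMID cited by more than ``max_genes_per_pmid`` genes (default 10) is
    removed everywhere; genes left without citations are removed too.
    """
    if not raw_map:
        raise ValueError("empty citation map")
    if max_genes_per_pmid < 1:
        raise ValueError("max_genes_per_pmid must be >= 1")
    genes_per_pmid: Counter[int] = Counter()
    for pmids in raw_map.values():
        genes_per_pmid.update(pmids)
    bad = {p for p, c in genes_per_pmid.items() if c > max_genes_per_pmid}
    out: dict[str, set[int]] = {}
    for gene, pmids in raw_map.items():
        kept = set(pmids) - bad
        if kept:
            out[gene] = kept
    if bad:
        logger.info("removed %d citations referring to > %d genes", len(bad), max_genes_per_pmid)
    return out


def build_pair_documents(corpus: CitationCorpus) -> list[PairDocument]:
    """One document per (non-TF gene, TF) pair sharing >= 1 citation.

    Text is the concatenation of each shared citation's title+abstract in
    ascending PMID order, which makes downstream term counts deterministic.
    Pairs are returned sorted by (gene, tf).
    """
    tfs = corpus.tfs
    if not tfs:
        raise ValueError("no TFs in corpus")
    docs: list[PairDocument] = []
    tf_pmids = {t: corpus.gene_to_pmids[t] for t in tfs}
    for gene in corpus.genes:
        gp = corpus.gene_to_pmids[gene]
        for tf in tfs:
            shared = gp & tf_pmids[tf]
            if shared:
                text = " ".join(corpus.abstracts[p] for p in sorted(shared))
                docs.append(PairDocument(gene, tf, frozenset(shared), text))
    return docs


def tokenize(
    text: str, stoplist: set[str] | frozenset[str] = frozenset(), drop_numeric: bool = False
) -> list[str]:
    """Split text into index terms.

    Lower-cases; every character that is not alphanumeric, hyphen or
    underscore acts as whitespace; leading/trailing hyphens are stripped
    from tokens; tokens shorter than three characters or on the stop list
    are removed.  Order and multiplicity are preserved (counts matter).
    With ``drop_numeric``, purely numeric tokens are removed as well.
    """
    out = []
    chars = [
        c if (c.isalnum() or c in "-_") else " "
        for c in text.lower()
    ]
    for raw in "".join(chars).split():
        tok = raw.strip("-")
        if len(tok) < 3 or tok in stoplist:
            continue
        if drop_numeric and tok.isdigit():
            continue
        out.append(tok)
    return out


def count_terms(
    docs: list[PairDocument],
    stoplist: set[str] | frozenset[str] = frozenset(),
    drop_numeric: bool = False,
) -> tuple[Vocabulary, list[str], list[str], list[tuple[int, int, int, int]]]:
    """Raw term counts per (gene, TF) pair in coordinate form.

    Returns ``(vocabulary, gene_labels, tf_labels, entries)`` where each
    entry is ``(term_idx, gene_idx, tf_idx, raw_count)`` with count > 0.
    All three index maps are lexicographic over the labels that survive.
    """
    if not docs:
        raise ValueError("no documents to count")
    genes = sorted({d.gene for d in docs})
    tfs = sorted({d.tf for d in docs})
    gi = {g: i for i, g in enumerate(genes)}
    ki = {t: i for i, t in enumerate(tfs)}
    per_pair: dict[tuple[int, int], Counter[str]] = {}
    all_terms: set[str] = set()
    for d in docs:
        counts = Counter(tokenize(d.text, stoplist, drop_numeric))
        if counts:
            per_pair[(gi[d.gene], ki[d.tf])] = counts
            all_terms.update(counts)
    if not all_terms:
        raise ValueError("empty vocabulary")
    vocab = Vocabulary.from_terms(all_terms)
    entries = [
        (vocab.term_to_index[t], j, k, c)
        for (j, k), counts in per_pair.items()
        for t, c in counts.items()
    ]
    entries.sort()
    return vocab, genes, tfs, entries


# ---------------------------------------------------------------------------
# Readers for the plain-text exchange formats.

def read_gene2pubmed(path: str | Path) -> dict[str, set[int]]:
    """gene2pubmed-style TSV (tax_id, GeneID, PubMed_ID; '#' header optional).

    Identifiers are matched case-insensitively and stored upper-cased.
    """
    out: dict[str, set[int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed gene2pubmed line: {line!r}")
            gene, pmid = fields[1].upper(), int(fields[2])
            out.setdefault(gene, set()).add(pmid)
    return out


def read_abstracts_jsonl(path: str | Path) -> dict[int, str]:
    """JSON Lines abstract store: one object per line with pmid/title/abstract."""
    out: dict[int, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            out[int(rec["pmid"])] = f"{rec.get('title', '')} {rec.get('abstract', '')}".strip()
    return out


def read_id_list(path: str | Path) -> set[str]:
    """Plain-text identifier list, one per line, stored upper-cased."""
    with open(path) as fh:
        return {line.strip().upper() for line in fh if line.strip() and not line.startswith("#")}


def read_stoplist(path: str | Path) -> frozenset[str]:
    """Plain-text stop list, one lower-cased term per line."""
    with open(path) as fh:
        return frozenset(
            line.strip().lower() for line in fh if line.strip() and not line.startswith("#")
        )


def default_stoplist() -> frozenset[str]:
    """The bundled English stop list."""
    text = resources.files("atmkit.data").joinpath("stopwords.txt").read_text()
    return frozenset(
        line.strip().lower() for line in text.splitlines() if line.strip() and not line.startswith("#")
    )


def load_corpus(
    gene2pubmed: str | Path,
    abstracts: str | Path,
    tf_list: str | Path,
    max_genes_per_pmid: int = 10,
    provenance: str = "",
) -> CitationCorpus:
    """Read the three input files, apply the citation filter and validate."""
    raw = read_gene2pubmed(gene2pubmed)
    filtered = filter_citations(raw, max_genes_per_pmid)
    corpus = CitationCorpus(
        gene_to_pmids=filtered,
        tf_ids=read_id_list(tf_list),
        abstracts=read_abstracts_jsonl(abstracts),
        provenance=provenance or str(gene2pubmed),
    )
    return corpus.validate()
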