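"""Seeded synthetic corpora and tensors with planted term–gene–TF blocks.

The generator plants disjoint (or overlapping) blocks — a set of terms, a
set of genes and a set of TFs that co-occur with elevated intensity — and
emits either the tensor directly or a full citation corpus (gene→PMID map,
bag-of-words abstracts, TF list, stop list, gold-standard GMT) from which
the pipeline should recover the blocks.  Everything derives from a single
integer seed through per-component child streams, so each artifact can be
regenerated independently.

Abstracts are bags of words, not prose: only term counts matter downstream.
Block vocabularies use a synthetic lexicon (``termNNNN``) so they cannot
collide with the stop list; the noise rate controls both the fraction of
filler words inside block abstracts and the rate of spurious background
structure (cross-block citations, background tensor entries).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np

from .corpus import CitationCorpus
from .tensor import SparseTensor3

__all__ = ["PlantedBlock", "PlantedModel", "SyntheticCorpus", "synth_tensor", "synth_corpus"]

# words injected as connective filler so the stop list has something to do
_STOPWORDS = ("the", "and", "for", "with", "from", "were", "this", "that")


@dataclass(frozen=True)
class PlantedBlock:
    terms: tuple[int, ...]
    genes: tuple[int, ...]
    tfs: tuple[int, ...]
    intensity: float = 1.0


@dataclass
class PlantedModel:
    """Ground-truth description of the planted structure."""

    n_terms: int
    n_genes: int
    n_tfs: int
    blocks: list[PlantedBlock]
    noise_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_terms, self.n_genes, self.n_tfs) < 1:
            raise ValueError("degenerate dims")
        if not self.blocks:
            raise ValueError("blocks must be non-empty")
        if not 0 <= self.noise_rate < 1:
            raise ValueError("noise_rate must be in [0, 1)")
        for b in self.blocks:
            if b.intensity <= 0:
                raise ValueError("block intensity must be positive")
            if (
                max(b.terms) >= self.n_terms
                or max(b.genes) >= self.n_genes
                or max(b.tfs) >= self.n_tfs
            ):
                raise ValueError("block subset out of range")

    @classmethod
    def disjoint(
        cls,
        n_blocks: int,
        terms_per_block: int = 30,
        genes_per_block: int = 10,
        tfs_per_block: int = 2,
        intensity: float = 5.0,
        noise_rate: float = 0.1,
        seed: int = 0,
    ) -> "PlantedModel":
        """Evenly partitioned non-overlapping blocks.

        Block intensities follow a decreasing geometric profile
        (``intensity * 0.8**b``): modules differ in literature volume, and
        distinct weights give the planted components a well-defined order.
        """
        blocks = [
            PlantedBlock(
                terms=tuple(range(b * terms_per_block, (b + 1) * terms_per_block)),
                genes=tuple(range(b * genes_per_block, (b + 1) * genes_per_block)),
                tfs=tuple(range(b * tfs_per_block, (b + 1) * tfs_per_block)),
                intensity=intensity * 0.8**b,
            )
            for b in range(n_blocks)
        ]
        return cls(
            n_terms=n_blocks * terms_per_block,
            n_genes=n_blocks * genes_per_block,
            n_tfs=n_blocks * tfs_per_block,
            blocks=blocks,
            noise_rate=noise_rate,
            seed=seed,
        )

    def _streams(self, n: int) -> list[np.random.Generator]:
        return [np.random.default_rng(s) for s in np.random.SeedSequence(self.seed).spawn(n)]


def synth_tensor(model: PlantedModel) -> tuple[SparseTensor3, dict]:
    """Planted-block tensor: Σ_b intensity·(1_terms ∘ 1_genes ∘ 1_tfs) + noise.

    Block entries receive multiplicative uniform noise of amplitude
    ``noise_rate``; additionally a fraction ``noise_rate`` of all cells get
    small background values.  Returns the tensor and a ground-truth dict.
    """
    rng_block, rng_bg = model._streams(2)
    dims = (model.n_terms, model.n_genes, model.n_tfs)
    entries: dict[tuple[int, int, int], float] = {}
    for blk in model.blocks:
        for i, j, k in product(blk.terms, blk.genes, blk.tfs):
            wobble = 1.0 + rng_block.uniform(-model.noise_rate, model.noise_rate)
            entries[(i, j, k)] = entries.get((i, j, k), 0.0) + blk.intensity * wobble
    total = dims[0] * dims[1] * dims[2]
    n_bg = int(round(model.noise_rate * total))
    if n_bg:
        mean_intensity = float(np.mean([b.intensity for b in model.blocks]))
        flat = rng_bg.choice(total, size=n_bg, replace=False)
        vals = rng_bg.uniform(0.0, model.noise_rate * mean_intensity, size=n_bg)
        for f, v in zip(flat, vals):
            if v <= 0:
                continue
            i, rem = divmod(int(f), dims[1] * dims[2])
            j, k = divmod(rem, dims[2])
            entries.setdefault((i, j, k), v)
    X = SparseTensor3.from_entries(dims, [(i, j, k, v) for (i, j, k), v in entries.items()])
    truth = {"blocks": model.blocks, "dims": dims, "noise_rate": model.noise_rate}
    return X, truth


@dataclass
class SyntheticCorpus:
    """A generated corpus plus its gold standard and ground truth."""

    corpus: CitationCorpus
    gene_sets: dict[str, tuple[str, str, set[str]]]  # id -> (name, description, members)
    stoplist: frozenset[str]
    truth: dict = field(default_factory=dict)

    def write_files(self, out_dir: str | Path) -> dict[str, Path]:
        """Write gene2pubmed TSV, abstracts JSONL, TF list, stop list, GMT."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "gene2pubmed": out / "gene2pubmed.tsv",
            "abstracts": out / "abstracts.jsonl",
            "tf_list": out / "tfs.txt",
            "stoplist": out / "stoplist.txt",
            "gmt": out / "gold.gmt",
        }
        with open(paths["gene2pubmed"], "w") as fh:
            fh.write("#tax_id\tGeneID\tPubMed_ID\n")
            for gene in sorted(self.corpus.gene_to_pmids):
                for pmid in sorted(self.corpus.gene_to_pmids[gene]):
                    fh.write(f"10090\t{gene}\t{pmid}\n")
        with open(paths["abstracts"], "w") as fh:
            for pmid in sorted(self.corpus.abstracts):
                text = self.corpus.abstracts[pmid]
                title, _, body = text.partition(". ")
                fh.write(json.dumps({"pmid": pmid, "title": title, "abstract": body}) + "\n")
        paths["tf_list"].write_text("".join(f"{t}\n" for t in sorted(self.corpus.tf_ids)))
        paths["stoplist"].write_text("".join(f"{w}\n" for w in sorted(self.stoplist)))
        with open(paths["gmt"], "w") as fh:
            for cid in sorted(self.gene_sets):
                name, desc, members = self.gene_sets[cid]
                fh.write("\t".join([cid, desc] + sorted(members)) + "\n")
        return paths


def synth_corpus(
    model: PlantedModel,
    abstracts_per_pair: int = 2,
    words_per_abstract: int = 60,
) -> SyntheticCorpus:
    """Citation corpus whose pair documents carry planted block vocabulary.

    Every within-block (gene, TF) pair shares ``abstracts_per_pair``
    citations whose bag-of-words texts draw from the block's term lexicon
    with probability 1 − noise_rate (filler/stop words otherwise).  A
    fraction ``noise_rate`` of cross-block pairs share one filler-only
    citation.  The gold-standard gene sets are the planted blocks.
    """
    rng_text, rng_noise = model._streams(2)
    genes = [f"GENE{a:04d}" for a in range(model.n_genes)]
    tfs = [f"TF{a:03d}" for a in range(model.n_tfs)]
    lexicon = [f"term{a:04d}" for a in range(model.n_terms)]
    filler = [f"filler{a:04d}" for a in range(max(20, model.n_terms // 4))]

    gene_to_pmids: dict[str, set[int]] = {}
    abstracts: dict[int, str] = {}
    pmid = 10_000_000

    def make_abstract(vocab: list[str], noise: float) -> str:
        words = []
        for _ in range(words_per_abstract):
            u = rng_text.uniform()
            if u < noise / 2:
                words.append(_STOPWORDS[rng_text.integers(len(_STOPWORDS))])
            elif u < noise:
                words.append(filler[rng_text.integers(len(filler))])
            else:
                words.append(vocab[rng_text.integers(len(vocab))])
        return " ".join(words)

    block_pairs: set[tuple[str, str]] = set()
    for blk in model.blocks:
        vocab = [lexicon[t] for t in blk.terms]
        for g_idx, t_idx in product(blk.genes, blk.tfs):
            g, t = genes[g_idx], tfs[t_idx]
            block_pairs.add((g, t))
            for _ in range(abstracts_per_pair):
                pmid += 1
                text = make_abstract(vocab, model.noise_rate)
                abstracts[pmid] = f"{text.split(' ', 1)[0]}. {text.split(' ', 1)[1]}"
                gene_to_pmids.setdefault(g, set()).add(pmid)
                gene_to_pmids.setdefault(t, set()).add(pmid)

    n_cross = int(round(model.noise_rate * len(block_pairs)))
    cross_candidates = [
        (g, t) for g, t in product(genes, tfs) if (g, t) not in block_pairs
    ]
    if n_cross and cross_candidates:
        picks = rng_noise.choice(len(cross_candidates), size=min(n_cross, len(cross_candidates)), replace=False)
        for idx in picks:
            g, t = cross_candidates[int(idx)]
            pmid += 1
            text = make_abstract(filler, 0.2)
            abstracts[pmid] = f"{text.split(' ', 1)[0]}. {text.split(' ', 1)[1]}"
            gene_to_pmids.setdefault(g, set()).add(pmid)
            gene_to_pmids.setdefault(t, set()).add(pmid)

    corpus = CitationCorpus(
        gene_to_pmids=gene_to_pmids,
        tf_ids=set(tfs),
        abstracts=abstracts,
        provenance=f"synthetic planted model seed={model.seed}",
    ).validate()

    gene_sets = {
        f"BLOCK{b}": (
            f"BLOCK{b}",
            " ".join(sorted(lexicon[t] for t in blk.terms)),
            {genes[g] for g in blk.genes} | {tfs[t] for t in blk.tfs},
        )
        for b, blk in enumerate(model.blocks)
    }
    truth = {
        "block_genes": [frozenset(genes[g] for g in b.genes) for b in model.blocks],
        "block_tfs": [frozenset(tfs[t] for t in b.tfs) for b in model.blocks],
        "block_terms": [frozenset(lexicon[t] for t in b.terms) for b in model.blocks],
        "genes": genes,
        "tfs": tfs,
    }
    return SyntheticCorpus(corpus, gene_sets, frozenset(_STOPWORDS), truth)
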