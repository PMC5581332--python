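# atmkit

Extraction and functional annotation of transcriptional modules from
biomedical literature by **non-negative tensor factorization (NTF)**.

Gene regulatory relationships are three-way: a set of genes, the
transcription factors (TFs) that regulate them, and the vocabulary the
literature uses to describe their interaction. `atmkit` represents a
corpus of gene–TF co-citations as a sparse 3-mode **term × gene × TF**
tensor and decomposes it into rank-1 components, each of which is read out
as an **annotated transcriptional module (ATM)**: a ranked set of genes, a
ranked set of TFs, and the ranked terms that functionally annotate their
relationship. It is aimed at computational biologists who want to mine
TF–target associations (including implicit ones) and candidate functional
annotations from abstracts, and at anyone who needs a compact, tested
sparse CP/PARAFAC solver with multiplicative updates.

## Method

1. **Corpus.** From a gene→PubMed citation map, citations referring to
   more than 10 genes are discarded. For every (gene, TF) pair sharing at
   least one citation, a document is built by concatenating the titles and
   abstracts of the shared citations. Documents are tokenized (punctuation
   except `-`/`_` removed, lower-cased, terms < 3 characters and stop
   words dropped).
2. **Tensor.** Term frequencies per pair form `f_ijk`, weighted as
   `l_ijk = log2(1 + f_ijk)` to damp ubiquitous terms.
3. **Decomposition.** The rank-k non-negative PARAFAC model

   `X ≈ Σ_{r=1..k} λ_r (a_r ∘ b_r ∘ c_r)`,  A, B, C ≥ 0

   is fitted by alternating multiplicative updates
   `F ← F ⊙ (X_(mode) Z) ⊘ (F ZᵀZ + ε)` with `Z` the Khatri–Rao product of
   the other two factors, SVD-based initialization, ε = 1e−9, and
   convergence on the change in fit (1 − relative Frobenius error,
   tolerance 1e−4). Columns are normalized to unit length and the weights
   λ sorted non-increasing.
4. **Modules.** Per component and mode, scores are truncated to the top
   300 terms / 184 genes / 21 TFs and cut at the entropy-derived count
   `s = max(1, |{p_i > E/n}|)` with `E = −Σ p_i log p_i / log n`.
5. **Evaluation.** Hypergeometric enrichment of each module's pooled
   genes+TFs against GMT gene sets; Mann–Whitney AUC of the ranked terms
   against tokenized category descriptions; precision against gold
   standards with a right-tailed Welch's t-test versus size-matched random
   gene–TF sets; Jaccard redundancy and per-run diversity coefficients;
   guilt-by-association and term-mapping category predictions.

A seeded synthetic generator plants term–gene–TF blocks and emits either
the tensor directly or a complete five-file corpus (citation map, JSONL
abstracts, TF list, stop list, gold-standard GMT), so the whole pipeline
runs and is tested entirely offline.

## Worked example

```python
from atmkit import (PlantedModel, build_pair_documents, count_terms, extract_atms,
                    hypergeom_enrich, ntf, synth_corpus)
from atmkit.tensor import from_term_counts

model = PlantedModel.disjoint(n_blocks=2, seed=7)   # 2 modules, 20 genes, 4 TFs
sim = synth_corpus(model)

docs = build_pair_documents(sim.corpus)
vocab, genes, tfs, entries = count_terms(docs, sim.stoplist)
X = from_term_counts(vocab, genes, tfs, entries)    # log2(1+f) weighted
print("tensor dims:", X.dims, "nnz:", X.nnz)

cp = ntf(X, k=2, random_state=7)
print(f"fit = {cp.fit:.3f} after {len(cp.fit_history)} sweeps, lambda = {cp.lam.round(1)}")

atms = extract_atms(cp)
universe = set(genes) | set(tfs)
for atm in atms:
    _, _, gold = sim.gene_sets[f"BLOCK{atm.component_index}"]
    p = hypergeom_enrich(atm.members, gold, universe).p_value
    print(f"ATM {atm.component_index}: {len(atm.genes)} genes, "
          f"{len(atm.tfs)} TFs, {len(atm.terms)} terms, enrichment p = {p:.2e}")
```

prints

```
tensor dims: (80, 20, 4) nnz: 1457
fit = 0.604 after 5 sweeps, lambda = [51.2 51.2]
ATM 0: 10 genes, 2 TFs, 30 terms, enrichment p = 3.70e-07
ATM 1: 10 genes, 2 TFs, 30 terms, enrichment p = 3.70e-07
```

Both planted modules are recovered exactly: each ATM contains precisely
the 10 genes, 2 TFs and 30 vocabulary terms of one planted block, and the
hypergeometric test confirms the match against the bundled gold standard
(p ≈ 4e−7 with a 24-identifier universe). The moderate fit (0.60) is
expected — the corpus route adds tokenization noise and filler vocabulary
on top of the planted structure.

The same pipeline is available from the shell:

```sh
atm simulate --blocks 2 --genes 20 --tfs 4 --seed 7 --out sim/
atm run --config run.yaml --ranks 1,2,3 --out run_out/
```

`atm run` executes corpus → tensor → factorization (one model per rank) →
module extraction → evaluation and writes a manifest with input hashes and
per-stage counts; re-running with the same config and seed reproduces the
outputs byte for byte.

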