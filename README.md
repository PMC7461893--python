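# semkos

Semi-automatic construction of hierarchical **knowledge organization
systems** (KOS) from full-text article corpora.

Manually curated vocabularies like MeSH are expensive to build and slow to
update. `semkos` implements an alternative workflow for a fast-moving field:
harvest the field's own vocabulary from full-text articles (author keywords,
and method names taken from the subtitles of "Materials and Methods"-like
sections), embed the terms, cluster them into a binary tree, and let a
curator name branches by inspecting only a handful of representative terms
per branch. The resulting two-level hierarchy then powers bibliometric
analyses: which methods are combined with which topics, how popular each
combination is, and what characterizes any group of articles.

## The pipeline

1. **Extraction** (`corpus_io`) — JATS/NXML files (the PubMed Central
   full-text dialect) are parsed into article records. A section is
   methods-like iff its lowercased title contains `method` or `procedure`;
   its immediate subsection titles are taken as method names. Citation
   counts come from a TSV side table.
2. **Lexicon** (`lexicon_tokenizer`) — surfaces are lowercased and ranked
   by frequency within kind (`kwd1` = most frequent keyword, `mtd1` = most
   frequent method; duplicates are kept only as methods). Keywords are
   retained if they occur > 5 times as keywords and > 10 times in the
   corpus; methods if > 2 times as subtitles and > 10 times in the corpus.
   Text is tokenized **longest-phrase-first**: scanning left to right, the
   longest lexicon phrase starting at each position is emitted and
   consumed, so `short-term memory` inside `visual short-term memory` is
   not counted; all other words are discarded.
3. **Embedding** (`embedding`) — joint term and document vectors (window 7,
   dimension 300, min count 10, 10 epochs, learning rate 0.025 decaying by
   0.002 per epoch by default) trained on the token streams; term vectors
   are normalized to unit length.
4. **Tree and KOS** (`tree_kos`) — average-linkage (UPGMA) agglomeration of
   the unit vectors under Euclidean distance. With n terms, leaves are
   labeled 1..n and the k-th merge creates node n+k (root 2n−1).
   `sample_branch_for_review` picks one leaf per deepest subtree so a
   curator can judge a branch from a small sample; named level-2 clusters
   (monophyletic branches, or several sibling branches sharing one name)
   are re-clustered via their mean member vectors into coarser level-3
   groups.
5. **Co-occurrence** (`cooccurrence`) — for an article with citation weight
   W, keyword-cluster counts K_i and method-cluster counts M_j, the
   correlation index is

   ```
   C_ij = W · K_i · M_j / Σ_{i,j} K_i · M_j
   ```

   so each article distributes exactly W over the cluster pairs it
   combines. Summed over the corpus this gives the keyword×method matrix;
   its log is the heat map, the top-k cells are the most popular
   combinations, and the histogram of cell values over [10, 400] at step 10
   is fitted by least squares in log-log space to a power law.
6. **Article analysis** (`article_analysis`) — a cluster doubles as a
   query: every article containing at least one member term belongs to its
   group. Groups are clustered by affinity propagation on document vectors,
   applied in rounds (round r clusters the exemplars of round r−1), and
   profiled by **coverage** (fraction of group articles containing a
   cluster term) or coverage difference against a reference group.

A synthetic-corpus generator (`synthetic_corpus`) emits JATS-like XML with
planted keyword/method groups, nested phrases, a keyword×method affinity
block and Zipf-distributed citations, plus the ground truth to score
recovery — the whole pipeline is testable without downloading anything.

## Worked example

Run the full pipeline on a generated corpus (500 articles, 5 planted
keyword groups, 4 method groups, with keyword group 2 × method group 3
combined 8× more often than chance):

```sh
semkos run --config config.json --out out
semkos topk --out out --k 5
```

```
114.231 kwd-cluster-1  mtd-cluster-3
94.3087 kwd-cluster-4  mtd-cluster-3
89.6487 kwd-cluster-5  mtd-cluster-3
70.2393 kwd-cluster-3  mtd-cluster-4
69.9271 kwd-cluster-2  mtd-cluster-3
```

The first column is the aggregated correlation index: the planted
high-affinity block tops the ranking, and its value is the citation mass
that articles spend on that combination. Reviewing a tree branch shows the
terms a curator would read before naming it:

```sh
semkos review --out out --node 59 --budget 4
# kwd2  kwd5  kwd6  kwd10
```

Profiling the articles retrieved by one keyword cluster
(`semkos profile --out out --cluster kwd-cluster-1`) writes a ranked
coverage table (`out/profile.tsv`):

```
ID  Cluster name   Coverage
1   kwd-cluster-2  0.00
...
5   mtd-cluster-3  100.00
6   mtd-cluster-4  91.07
```

Every article in the group mentions a `mtd-cluster-3` method, while other
keyword clusters are absent — the generated topics are disjoint, and the
retrieval cluster itself is excluded from its own ranking.

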