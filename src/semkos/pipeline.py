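"""Orchestration: run the full extract-to-profile pipeline from one config.

The run configuration is a single JSON document. Each stage writes its
artifacts into the output directory and records a cache key derived from
its own parameters and the hashes of its upstream artifacts, so re-running
an unchanged config skips every stage and reproduces identical hashes -
cheap re-runs are what makes the manual branch-review loop practical.
A manifest lists every produced file with its content hash, and one JSON
log line per event makes a run auditable.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from pathlib import Path
from typing import Any, Callable

from semkos import corpus_io, lexicon_tokenizer as lt
from semkos.article_analysis import profile_article_group, retrieve_articles, write_profile_tsv
from semkos.cooccurrence import (
    bin_correlation_counts,
    correlation_from_streams,
    rank_top_combinations,
)
from semkos.embedding import (
    EmbeddingConfig,
    VectorTable,
    normalize_vectors,
    read_word2vec_text,
    train_embeddings,
    write_word2vec_text,
)
from semkos.synthetic_corpus import PlantedSpec, generate_corpus, write_corpus
from semkos.tree_kos import (
    KOS,
    agglomerate_average_linkage,
    annotate_from_cut,
    export_tree,
    pairwise_distances,
    read_kos_tsv,
    regroup_level3,
    tree_from_json,
    write_kos_tsv,
)

__all__ = ["run_pipeline", "load_config", "PIPELINE_STAGES", "PipelineError"]

PIPELINE_STAGES = (
    "synth",
    "extract",
    "lexicon",
    "tokenize",
    "embed",
    "cluster",
    "kos",
    "correlate",
    "profile",
)


class PipelineError(RuntimeError):
    pass


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _key(params: Any, upstream_hashes: list[str]) -> str:
    payload = json.dumps({"params": params, "upstream": upstream_hashes}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def load_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        config = json.load(fh)
    if not isinstance(config, dict):
        raise PipelineError("config: top level must be a JSON object")
    return config


class _Run:
    def __init__(self, config: dict, log_stream=None):
        self.config = config
        self.out = Path(config["out_dir"])
        self.seed = int(config.get("seed", 0))
        self.manifest: dict[str, str] = {}
        self.stage_keys: dict[str, str] = {}
        self.log_stream = log_stream if log_stream is not None else sys.stderr

    def log(self, **event) -> None:
        event.setdefault("ts", round(time.time(), 3))
        print(json.dumps(event, sort_keys=True), file=self.log_stream)

    def artifact(self, name: str) -> Path:
        return self.out / name

    def record(self, *names: str) -> None:
        for name in names:
            self.manifest[name] = _sha256(self.artifact(name))

    def need(self, name: str, producer: str) -> Path:
        p = self.artifact(name)
        if not p.exists():
            raise PipelineError(
                f"missing upstream artifact {name!r}; run stage {producer!r} first"
            )
        return p

    def cached(self, stage: str, params: Any, upstream: list[str], outputs: list[str]) -> bool:
        key = _key(params, [self.manifest.get(u) or _sha256(self.artifact(u)) for u in upstream])
        self.stage_keys[stage] = key
        key_file = self.artifact(f".{stage}.key")
        if key_file.exists() and key_file.read_text() == key and all(
            self.artifact(o).exists() for o in outputs
        ):
            self.record(*outputs)
            self.log(stage=stage, event="cached")
            return True
        return False

    def done(self, stage: str, outputs: list[str]) -> None:
        self.artifact(f".{stage}.key").write_text(self.stage_keys[stage])
        self.record(*outputs)
        self.log(stage=stage, event="done", outputs=outputs)


def _stage_synth(run: _Run) -> None:
    params = dict(run.config.get("synth", {}))
    params.setdefault("seed", run.seed)
    outputs = ["corpus/citations.tsv", "corpus/ground_truth.json"]
    if run.cached("synth", params, [], outputs):
        return
    spec_kwargs = dict(params)
    if "nested_phrase_pairs" in spec_kwargs:
        spec_kwargs["nested_phrase_pairs"] = tuple(
            tuple(p) for p in spec_kwargs["nested_phrase_pairs"]
        )
    if spec_kwargs.get("affinity_block") is not None:
        spec_kwargs["affinity_block"] = tuple(spec_kwargs["affinity_block"])
    records, truth = generate_corpus(PlantedSpec(**spec_kwargs))
    write_corpus(records, truth, run.artifact("corpus"))
    run.log(stage="synth", n_articles=len(records))
    run.done("synth", outputs)


def _stage_extract(run: _Run) -> None:
    inp = run.config.get("input", {})
    articles_path = inp.get("articles") or str(run.artifact("corpus"))
    citations_path = inp.get("citations") or str(run.artifact("corpus") / "citations.tsv")
    params = {"articles": articles_path, "citations": citations_path}
    if run.cached("extract", params, [], ["articles.jsonl"]):
        return
    citations = corpus_io.read_citation_table(citations_path) if Path(citations_path).exists() else {}
    records = corpus_io.read_jats_articles(articles_path, citations)
    corpus_io.write_article_jsonl(records, run.artifact("articles.jsonl"))
    run.log(stage="extract", articles_read=len(records))
    run.done("extract", ["articles.jsonl"])


def _stage_lexicon(run: _Run) -> None:
    run.need("articles.jsonl", "extract")
    if run.cached("lexicon", {}, ["articles.jsonl"], ["lexicon_raw.tsv"]):
        return
    records = corpus_io.read_article_jsonl(run.artifact("articles.jsonl"))
    lexicon = lt.build_lexicon(records)
    lt.write_lexicon_tsv(lexicon, run.artifact("lexicon_raw.tsv"))
    run.log(stage="lexicon", terms=len(lexicon))
    run.done("lexicon", ["lexicon_raw.tsv"])


def _stage_tokenize(run: _Run) -> None:
    run.need("articles.jsonl", "extract")
    run.need("lexicon_raw.tsv", "lexicon")
    params = dict(run.config.get("lexicon_filter", {}))
    outputs = ["lexicon.tsv", "streams.jsonl"]
    if run.cached("tokenize", params, ["articles.jsonl", "lexicon_raw.tsv"], outputs):
        return
    records = corpus_io.read_article_jsonl(run.artifact("articles.jsonl"))
    raw = lt.read_lexicon_tsv(run.artifact("lexicon_raw.tsv"))
    raw_streams = lt.tokenize_corpus(records, raw)
    counts = lt.corpus_counts(raw_streams, raw)
    filtered = lt.filter_lexicon(raw, counts, **params)
    streams = lt.tokenize_corpus(records, filtered)
    lt.write_lexicon_tsv(filtered, run.artifact("lexicon.tsv"))
    lt.write_token_streams(streams, run.artifact("streams.jsonl"))
    run.log(stage="tokenize", terms_kept=len(filtered), streams=len(streams))
    run.done("tokenize", outputs)


def _stage_embed(run: _Run) -> None:
    run.need("streams.jsonl", "tokenize")
    params = dict(run.config.get("embedding", {}))
    params.setdefault("random_seed", run.seed)
    outputs = ["term_vectors.w2v", "doc_vectors.w2v"]
    if run.cached("embed", params, ["streams.jsonl"], outputs):
        return
    streams = lt.read_token_streams(run.artifact("streams.jsonl"))
    table = train_embeddings(streams, EmbeddingConfig(**params))
    write_word2vec_text(table.term_vectors, run.artifact("term_vectors.w2v"))
    write_word2vec_text(table.doc_vectors, run.artifact("doc_vectors.w2v"))
    run.log(stage="embed", terms=len(table.term_vectors), docs=len(table.doc_vectors))
    run.done("embed", outputs)


def _load_vectors(run: _Run) -> VectorTable:
    return VectorTable(
        term_vectors=read_word2vec_text(run.need("term_vectors.w2v", "embed")),
        doc_vectors=read_word2vec_text(run.need("doc_vectors.w2v", "embed")),
    )


def _stage_cluster(run: _Run) -> None:
    run.need("term_vectors.w2v", "embed")
    outputs = ["kwd_tree.json", "mtd_tree.json", "kwd_tree.nwk", "mtd_tree.nwk"]
    if run.cached("cluster", {}, ["term_vectors.w2v"], outputs):
        return
    table = normalize_vectors(_load_vectors(run))
    for kind, prefix in (("kwd", "kwd"), ("mtd", "mtd")):
        term_ids = sorted(
            (t for t in table.term_vectors if t.startswith(prefix)),
            key=lambda t: int(t[3:]),
        )
        if len(term_ids) < 2:
            raise PipelineError(f"fewer than 2 {kind} terms with vectors; cannot cluster")
        tree = agglomerate_average_linkage(pairwise_distances(table, term_ids), term_ids)
        run.artifact(f"{kind}_tree.json").write_text(export_tree(tree, "json"))
        run.artifact(f"{kind}_tree.nwk").write_text(export_tree(tree, "newick"))
        run.log(stage="cluster", kind=kind, tree_size=tree.n_nodes)
    run.done("cluster", outputs)


def _stage_kos(run: _Run) -> None:
    params = dict(run.config.get("kos", {}))
    outputs = ["kwd_kos.tsv", "mtd_kos.tsv"]
    upstream = ["kwd_tree.json", "mtd_tree.json", "term_vectors.w2v"]
    for u in upstream:
        run.need(u, "cluster" if u.endswith("json") else "embed")
    if run.cached("kos", params, upstream, outputs):
        return
    table = normalize_vectors(_load_vectors(run))
    for kind, default_k in (("kwd", 10), ("mtd", 5)):
        tree = tree_from_json(run.artifact(f"{kind}_tree.json").read_text())
        k = min(int(params.get(f"{kind}_clusters", default_k)), tree.n_leaves)
        kos = annotate_from_cut(KOS(tree), k, prefix=f"{kind}-cluster")
        if len(kos.level2()) >= 2:
            regroup_level3(kos, table, n_groups=params.get(f"{kind}_level3"))
        write_kos_tsv(kos, run.artifact(f"{kind}_kos.tsv"))
        run.log(stage="kos", kind=kind, level2=len(kos.level2()), level3=len(kos.level3()))
    run.done("kos", outputs)


def _load_kos(run: _Run, kind: str) -> KOS:
    tree = tree_from_json(run.need(f"{kind}_tree.json", "cluster").read_text())
    return read_kos_tsv(tree, run.need(f"{kind}_kos.tsv", "kos"))


def _citations(run: _Run) -> dict[str, int]:
    records = corpus_io.read_article_jsonl(run.need("articles.jsonl", "extract"))
    return {r.article_id: r.citation_count for r in records}


def _stage_correlate(run: _Run) -> None:
    upstream = ["streams.jsonl", "kwd_kos.tsv", "mtd_kos.tsv"]
    for u, s in zip(upstream, ("tokenize", "kos", "kos")):
        run.need(u, s)
    outputs = ["correlation.tsv", "correlation_bins.csv", "top_combinations.tsv"]
    if run.cached("correlate", {}, upstream, outputs):
        return
    streams = lt.read_token_streams(run.artifact("streams.jsonl"))
    kwd_kos, mtd_kos = _load_kos(run, "kwd"), _load_kos(run, "mtd")
    matrix = correlation_from_streams(streams, kwd_kos, mtd_kos, _citations(run))
    matrix.to_tsv(run.artifact("correlation.tsv"))
    bins = bin_correlation_counts(matrix)
    bins.to_csv(run.artifact("correlation_bins.csv"))
    with open(run.artifact("top_combinations.tsv"), "w", encoding="utf-8") as fh:
        fh.write("keyword_cluster\tmethod_cluster\tcorrelation_index\n")
        for kc, mc, v in rank_top_combinations(matrix, 20):
            fh.write(f"{kc}\t{mc}\t{v:.6g}\n")
    run.log(stage="correlate", matrix_mass=matrix.total())
    run.done("correlate", outputs)


def _stage_profile(run: _Run) -> None:
    params = dict(run.config.get("profile", {}))
    upstream = ["streams.jsonl", "kwd_kos.tsv", "mtd_kos.tsv", "articles.jsonl"]
    outputs = ["profile.tsv"]
    if run.cached("profile", params, upstream, outputs):
        return
    streams = lt.read_token_streams(run.artifact("streams.jsonl"))
    kwd_kos, mtd_kos = _load_kos(run, "kwd"), _load_kos(run, "mtd")
    cluster_name = params.get("cluster") or kwd_kos.level2()[0].name
    ann = kwd_kos.annotation_by_name(cluster_name)
    group = retrieve_articles(ann, kwd_kos, streams)
    profile = profile_article_group(
        group,
        streams,
        kwd_kos,
        mtd_kos,
        _citations(run),
        k=int(params.get("k", 10)),
        exclude_keyword_clusters={cluster_name},
    )
    write_profile_tsv(profile, run.artifact("profile.tsv"))
    run.log(stage="profile", cluster=cluster_name, group_size=len(group))
    run.done("profile", outputs)


_STAGE_FN: dict[str, Callable[[_Run], None]] = {
    "synth": _stage_synth,
    "extract": _stage_extract,
    "lexicon": _stage_lexicon,
    "tokenize": _stage_tokenize,
    "embed": _stage_embed,
    "cluster": _stage_cluster,
    "kos": _stage_kos,
    "correlate": _stage_correlate,
    "profile": _stage_profile,
}


def run_pipeline(config: dict, log_stream=None) -> dict[str, str]:
    """Execute the configured stages in order; returns the artifact manifest.

    Stages are validated before anything is written; an unknown stage name
    aborts with no partial output. Each stage is skipped when its cache key
    (parameters + upstream hashes) is unchanged and its outputs exist.
    """
    if "out_dir" not in config:
        raise PipelineError("config: missing field 'out_dir'")
    stages = config.get("stages") or [s for s in PIPELINE_STAGES if s != "synth"]
    unknown = [s for s in stages if s not in _STAGE_FN]
    if unknown:
        raise PipelineError(f"unknown stage names: {unknown}; valid: {list(PIPELINE_STAGES)}")
    run = _Run(config, log_stream=log_stream)
    run.out.mkdir(parents=True, exist_ok=True)
    ordered = [s for s in PIPELINE_STAGES if s in stages]
    for stage in ordered:
        _STAGE_FN[stage](run)
    run.manifest = dict(sorted(run.manifest.items()))
    manifest_path = run.artifact("manifest.json")
    manifest_path.write_text(
        json.dumps({"seed": run.seed, "files": run.manifest}, indent=1, sort_keys=True)
    )
    run.log(event="manifest", files=len(run.manifest))
    return run.manifest
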