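"""End-to-end pipeline: simulate -> preprocess -> train -> expand -> count
-> cooccur -> map, with a manifest making every run auditable.

One global seed derives per-stage seeds through a stable hash
(sha256 of "<seed>/<stage>", first 4 bytes, mod 2^31), so stages can be
rerun independently yet reproducibly.  The manifest records the config
hash, per-stage record counts and artifact checksums; it contains no
timestamps, so identical config + seed yields an identical manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import corpus as corpus_io
from .corpus import Corpus
from .cooccurrence import build_mention_table, cooccur, normalized_profiles, \
    ordering_report
from .lexicon import Lexicon, apply_curation, expand, save_lexicons_tsv
from .salience import project, save_summary
from .sgns import TrainingConfig, save_model, train
from .synthetic import SyntheticSpec, generate_corpus
from .text import merge_phrases, score_bigrams, tokenize_corpus

log = logging.getLogger(__name__)

DEFAULT_SYMPTOM_SEEDS = {
    "breathlessness": ["breathlessness"],
    "cough": ["cough"],
    "sputum": ["sputum"],
}
DEFAULT_IMPACT_SEEDS = {
    "anxiety": ["anxiety"], "depression": ["depression"],
    "fatigue": ["fatigue"], "pain": ["pain"], "exercise": ["exercise"],
}
# Severity term lists are a reconstruction: the analysis needs mild /
# moderate / severe lexicons but no canonical list exists, so they are
# configuration-supplied seed lists expanded like any other lexicon.
DEFAULT_SEVERITY_SEEDS = {
    "severity_mild": ["mild"],
    "severity_moderate": ["moderate"],
    "severity_severe": ["severe"],
}


def stage_seed(global_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{global_seed}/{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


@dataclass
class PipelineConfig:
    out_dir: str = "plm_run"
    corpus_path: str | None = None            # JSONL input, or None to simulate
    synthetic: dict | None = None             # SyntheticSpec fields
    phrase_min_count: int = 5
    phrase_discount: float = 5.0
    phrase_threshold: float = 10.0
    phrase_passes: int = 2
    training: dict = field(default_factory=dict)  # TrainingConfig overrides
    lexicon_seeds: dict[str, list[str]] = field(default_factory=dict)
    k_per_seed: int = 25
    min_similarity: float = 0.4
    expansion_rounds: int = 1
    curation: dict[str, dict] = field(default_factory=dict)  # name -> {accept, reject}
    rows: list[str] = field(default_factory=list)
    cols: list[str] = field(default_factory=list)
    reference_lexicon: str | None = None
    scanned_post_ids: str | None = None       # optional file restricting the scan
    rng_seed: int = 0

    def validate(self) -> None:
        if self.phrase_passes < 1:
            raise ValueError("phrase_passes must be >= 1")
        TrainingConfig(**self.training).validate()
        if self.synthetic is not None:
            SyntheticSpec.from_dict(self.synthetic)

    def to_yaml(self) -> str:
        d = asdict(self)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text) or {}
        known = {f for f in cls.__dataclass_fields__ if not f.startswith("_")}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order, writing artifacts and a manifest.

    Any stage error aborts with the stage name; partial outputs are kept
    next to a FAILED marker file.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.config_hash(),
                      "rng_seed": config.rng_seed, "stages": {}, "artifacts": {}}
    (out / "config.yaml").write_text(config.to_yaml(), encoding="utf-8")

    stage = "simulate"
    try:
        if config.synthetic is not None:
            spec_d = dict(config.synthetic)
            spec_d.setdefault("rng_seed", stage_seed(config.rng_seed, stage))
            spec = SyntheticSpec.from_dict(spec_d)
            corpus, truth = generate_corpus(spec)
            corpus_io.write_jsonl(corpus, out / "corpus.jsonl")
            with open(out / "truth.json", "w", encoding="utf-8") as fh:
                json.dump({"term_to_group": truth.term_to_group,
                           "post_groups": {k: sorted(v) for k, v in
                                           truth.post_groups.items()},
                           "expected_cooccurrence": {
                               f"{a}|{b}": v for (a, b), v in
                               truth.expected_cooccurrence.items()}}, fh)
            manifest["stages"][stage] = {"n_posts": len(corpus)}
        else:
            if not config.corpus_path:
                raise FileNotFoundError("no corpus_path and no synthetic spec")
            if not Path(config.corpus_path).exists():
                raise FileNotFoundError(f"corpus not found: {config.corpus_path}")
            corpus = corpus_io.read_jsonl(config.corpus_path)
            manifest["stages"][stage] = {"n_posts": len(corpus),
                                         "input": config.corpus_path,
                                         "input_sha": _sha256(Path(config.corpus_path))}

        stage = "preprocess"
        corpus = tokenize_corpus(corpus) if any(
            p.tokens is None for p in corpus) else corpus
        table = score_bigrams(corpus, config.phrase_min_count,
                              config.phrase_discount)
        corpus = merge_phrases(corpus, table, config.phrase_threshold,
                               config.phrase_passes)
        if config.scanned_post_ids:
            keep = set(Path(config.scanned_post_ids)
                       .read_text(encoding="utf-8").split())
            corpus = Corpus([p for p in corpus if p.id in keep])
            manifest["stages"].setdefault(stage, {})["scanned_filter"] = \
                config.scanned_post_ids
        corpus_io.write_jsonl(corpus, out / "tokenized.jsonl")
        manifest["stages"][stage] = {**manifest["stages"].get(stage, {}),
                                     "n_posts": len(corpus),
                                     "n_tokens": corpus.n_tokens,
                                     "n_bigrams_scored": len(table.scores)}

        stage = "train"
        tcfg = TrainingConfig(**{"rng_seed": stage_seed(config.rng_seed, stage),
                                 **config.training})
        model = train(corpus, tcfg)
        save_model(model, out / "model.vec")
        manifest["stages"][stage] = {
            "vocab_size": len(model.vocab),
            "final_mean_loss": model.epoch_mean_loss[-1]}

        stage = "expand"
        seeds_by_name = config.lexicon_seeds or {
            **DEFAULT_SYMPTOM_SEEDS, **DEFAULT_IMPACT_SEEDS,
            **DEFAULT_SEVERITY_SEEDS}
        lex_dir = out / "lexicons"
        lex_dir.mkdir(exist_ok=True)
        lexicons: list[Lexicon] = []
        for name in sorted(seeds_by_name):
            lex = expand(model, seeds_by_name[name], config.k_per_seed,
                         config.min_similarity, config.expansion_rounds,
                         name=name)
            cur = config.curation.get(name)
            if cur:
                lex = apply_curation(lex, cur.get("accept"), cur.get("reject"))
            lex.save(lex_dir / f"{name}.json")
            lexicons.append(lex)
        save_lexicons_tsv(lexicons, out / "lexicons.tsv")
        manifest["stages"][stage] = {
            lex.name: len(lex.active_terms) for lex in lexicons}

        stage = "count"
        mentions = build_mention_table(corpus, lexicons)
        mentions.save(out / "mentions.json")
        manifest["stages"][stage] = {
            name: e.mention_post_count for name, e in mentions.entries.items()}

        stage = "cooccur"
        names = [lex.name for lex in lexicons]
        rows = config.rows or [n for n in names if n in DEFAULT_SYMPTOM_SEEDS]
        cols = config.cols or [n for n in names if n not in rows]
        matrix = cooccur(mentions, rows, cols)
        matrix.to_tsv(out / "cooccurrence.tsv")
        report = ordering_report(normalized_profiles(matrix, "by-row"))
        with open(out / "ordering.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=1)
        manifest["stages"][stage] = {"rows": rows, "cols": cols,
                                     "total": int(matrix.counts.values.sum())}

        stage = "map"
        smap = project(model, lexicons, n_components=2)
        smap.to_tsv(out / "salience.tsv")
        save_summary(smap, config.reference_lexicon, out / "salience.json")
        manifest["stages"][stage] = {"n_points": len(smap.coords),
                                     "n_skipped": len(smap.skipped)}
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\n{exc}\n", encoding="utf-8")
        raise StageError(stage, exc) from exc

    for artifact in sorted(out.iterdir()):
        if artifact.is_file() and artifact.name != "manifest.json":
            manifest["artifacts"][artifact.name] = _sha256(artifact)
    for artifact in sorted((out / "lexicons").iterdir()):
        manifest["artifacts"][f"lexicons/{artifact.name}"] = _sha256(artifact)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
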