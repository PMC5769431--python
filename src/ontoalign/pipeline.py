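"""End-to-end matching pipeline: loading, matching, filtering.

The pipeline mirrors the architecture of mature biomedical ontology
matchers: ontologies are loaded into lexicons and relationship maps;
hash-based matchers run first and their output seeds the less precise
ones; preliminary alignments are combined hierarchically in decreasing
order of matcher precision (lexical > cross-reference/mediating >
logical definitions > thesaurus > word overlap > seed-local string
matching); cardinality selection and coherence repair produce the final
alignment.  A report with per-stage mapping counts and comparison
counters is returned alongside the alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .alignment import Alignment
from .background import (
    BKSource,
    build_bridge,
    lexical_expansion,
    logicaldef_match,
    mediating_match,
    select_bk,
    xref_match,
)
from .config import DEFAULT_CONFIG, MatchConfig
from .filtering import repair as repair_alignment
from .filtering import select
from .matchers import (
    combine,
    lexical_match,
    string_match_local,
    thesaurus_match,
    word_match,
)
from .model import (
    Lexicon,
    Ontology,
    build_lexicon,
    build_thesaurus,
    generate_reduced_synonyms,
)
from .obo import load_ontology

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """What to match and which pipeline components to enable."""

    source: Ontology | str = ""
    target: Ontology | str = ""
    bk_sources: list[Ontology | str] = field(default_factory=list)
    bk_mode: str = "mediator"  # "mediator" | "expansion"
    bk_info: str = "lexical"  # "lexical" | "xref"
    select_mode: str = "permissive"
    do_repair: bool = True
    use_reduced_synonyms: bool = True
    use_thesaurus: bool = True
    use_word_matcher: bool = True
    use_string_matcher: bool = True
    use_logical_defs: bool = True
    use_weights: bool = True
    match: MatchConfig = field(default_factory=lambda: DEFAULT_CONFIG)


@dataclass
class PipelineResult:
    alignment: Alignment
    report: dict

    def __iter__(self):
        return iter((self.alignment, self.report))


def _as_ontology(value: Ontology | str, stage: str) -> Ontology:
    if isinstance(value, Ontology):
        return value
    try:
        return load_ontology(value)
    except Exception as exc:
        raise RuntimeError(f"[{stage}] failed to load {value!r}: {exc}") from exc


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run loading -> matcher stack -> selection -> repair."""
    report: dict = {"stages": []}

    def log_stage(name: str, alignment: Optional[Alignment] = None, **extra) -> None:
        entry = {"stage": name, **extra}
        if alignment is not None:
            entry["mappings"] = len(alignment)
            entry.update(alignment.stats)
        report["stages"].append(entry)

    # --- loading ------------------------------------------------------------
    onto_a = _as_ontology(config.source, "loading")
    onto_b = _as_ontology(config.target, "loading")
    match_cfg = config.match if config.use_weights else config.match.with_uniform_weights()
    lex_a = build_lexicon(onto_a, match_cfg)
    lex_b = build_lexicon(onto_b, match_cfg)
    if config.use_reduced_synonyms:
        lex_a = generate_reduced_synonyms(lex_a, match_cfg)
        lex_b = generate_reduced_synonyms(lex_b, match_cfg)
    log_stage("loading", entries_a=len(lex_a), entries_b=len(lex_b))

    # --- background knowledge ----------------------------------------------
    bk_candidates = [
        BKSource(
            name=str(raw) if not isinstance(raw, Ontology) else raw.prefix,
            ontology=(bk_onto := _as_ontology(raw, "loading-bk")),
            lexicon=build_lexicon(bk_onto, match_cfg),
        )
        for raw in config.bk_sources
    ]
    selected = select_bk(
        bk_candidates,
        lex_a,
        lex_b,
        config=match_cfg,
        ontoA=onto_a,
        ontoB=onto_b,
        info=config.bk_info,
    ) if bk_candidates else []
    log_stage(
        "bk-selection",
        candidates=len(bk_candidates),
        selected=[bk.name for bk in selected],
    )

    # --- matcher stack, most precise first ----------------------------------
    combined = lexical_match(lex_a, lex_b, threshold=match_cfg.storage_threshold)
    log_stage("lexical", combined)

    for bk in selected:
        if config.bk_info == "xref":
            bk_alignment = xref_match(onto_a, onto_b, bk, lex_a, lex_b, match_cfg)
        else:
            bk_alignment = mediating_match(lex_a, lex_b, bk)
        if config.bk_mode == "expansion":
            lex_a = lexical_expansion(lex_a, bk.lexicon, bk.anchors_a, match_cfg)
            lex_b = lexical_expansion(lex_b, bk.lexicon, bk.anchors_b, match_cfg)
            bk_alignment = lexical_match(
                lex_a, lex_b, threshold=match_cfg.storage_threshold
            )
        combined = combine(combined, bk_alignment, "hierarchical")
        log_stage(f"bk-{bk.name}-{config.bk_mode}", bk_alignment)

    if config.use_logical_defs and onto_a.logical_defs and onto_b.logical_defs:
        bridge = build_bridge(*[bk.ontology for bk in selected]) if selected else {}
        ld = logicaldef_match(onto_a, onto_b, bridge, match_cfg)
        combined = combine(combined, ld, "hierarchical")
        log_stage("logicaldef", ld)

    if config.use_thesaurus:
        thes_a = build_thesaurus(lex_a)
        thes_b = build_thesaurus(lex_b)
        th = thesaurus_match(
            lex_a,
            lex_b,
            thes_a,
            thes_b,
            threshold=match_cfg.storage_threshold,
            config=match_cfg,
        )
        combined = combine(combined, th, "hierarchical")
        log_stage("thesaurus", th, pairs_a=len(thes_a), pairs_b=len(thes_b))

    if config.use_word_matcher:
        wm = word_match(lex_a, lex_b, config=match_cfg)
        combined = combine(combined, wm, "hierarchical")
        log_stage("word", wm)

    if config.use_string_matcher:
        sm = string_match_local(
            combined, onto_a, onto_b, lex_a, lex_b, config=match_cfg
        )
        combined = combine(combined, sm, "hierarchical")
        log_stage("string-local", sm)

    # --- filtering -----------------------------------------------------------
    selected_alignment = select(
        combined, config.select_mode, match_cfg.hybrid_threshold
    )
    log_stage(f"select-{config.select_mode}", selected_alignment)
    final = selected_alignment
    if config.do_repair:
        final = repair_alignment(selected_alignment, onto_a, onto_b)
        log_stage("repair", final, removed=len(selected_alignment) - len(final))

    report["final_mappings"] = len(final)
    return PipelineResult(final, report)


def pipeline_config_for_fixture(
    onto_a: Ontology,
    onto_b: Ontology,
    bk: Ontology | None = None,
    **overrides,
) -> PipelineConfig:
    """Convenience constructor used by tests and the CLI on fixtures."""
    cfg = PipelineConfig(source=onto_a, target=onto_b)
    if bk is not None:
        cfg.bk_sources = [bk]
    for key, value in overrides.items():
        if key == "match" and isinstance(value, dict):
            cfg.match = replace(cfg.match, **value)
        else:
            setattr(cfg, key, value)
    return cfg
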