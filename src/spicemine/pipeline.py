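"""End-to-end convenience workflow over the library modules.

Chains the stages a shell user would run one by one: simulate ->
ingest -> tag -> extract -> train -> classify -> score -> recommend ->
explain.  Primarily used for smoke testing and for reproducing the
synthetic-study results; each stage remains independently callable.
"""

from __future__ import annotations

from dataclasses import dataclass
from random import Random
from typing import Sequence

from spicemine.candidates import (
    CandidateInstance,
    attach_features,
    enumerate_pairs,
    normalize_tokens,
    segment_sentences,
    select_candidates,
)
from spicemine.lexicon import AbstractRecord, SpiceLexicon
from spicemine.ner import (
    build_disease_matcher,
    build_matcher,
    tag_diseases,
    tag_spices,
)
from spicemine.ontology import DiseaseOntology
from spicemine.relation import (
    Metrics,
    SvmRelationModel,
    evaluate,
    oversample,
    train_svm,
)
from spicemine.scoring import AssociationTable, SpectrumReport, aggregate
from spicemine.synthetic import (
    GroundTruth,
    SyntheticConfig,
    generate_corpus,
    generate_lexicon,
    generate_ontology,
    generate_phytochem_tables,
)
from spicemine.tripartite import ExplanationReport, explain

__all__ = ["extract_instances", "PipelineResult", "run_synthetic_study"]


def extract_instances(
    records: Sequence[AbstractRecord],
    lexicon: SpiceLexicon,
    ontology: DiseaseOntology,
    with_features: bool = True,
) -> list[CandidateInstance]:
    """Segment, tag and enumerate masked pair instances for a corpus."""
    spice_matcher = build_matcher(lexicon)
    disease_matcher = build_disease_matcher(ontology)
    instances: list[CandidateInstance] = []
    for rec in records:
        for s_idx, sentence in enumerate(segment_sentences(rec.abstract_text)):
            tokens = normalize_tokens(sentence)
            mentions = tag_spices(
                tokens, spice_matcher, rec.pmid, s_idx
            ) + tag_diseases(tokens, disease_matcher, rec.pmid, s_idx)
            if not select_candidates(mentions):
                continue
            for inst in enumerate_pairs(rec.pmid, s_idx, tokens, mentions):
                instances.append(attach_features(inst) if with_features else inst)
    return instances


def label_from_truth(
    instances: Sequence[CandidateInstance], truth: GroundTruth
) -> list[CandidateInstance]:
    """Attach gold labels to instances that have a planted label."""
    labeled = []
    for inst in instances:
        key = (inst.doc_id, inst.sentence_index, inst.spice_id, inst.disease_id)
        label = truth.labels.get(key)
        if label is not None:
            inst.label = label
            labeled.append(inst)
    return labeled


@dataclass
class PipelineResult:
    instances: list[CandidateInstance]
    model: SvmRelationModel
    test_metrics: Metrics
    table: AssociationTable
    report: SpectrumReport
    explanation: ExplanationReport
    truth: GroundTruth


def run_synthetic_study(
    cfg: SyntheticConfig,
    train_fraction: float = 0.8,
    svm_c: float = 1.0,
) -> PipelineResult:
    """Run the whole pipeline on one synthetic corpus.

    Generates the inputs, extracts and labels candidate instances,
    trains the SVM engine on a seeded shuffle split (oversampling the
    training part only), classifies the held-out part, aggregates
    predicted associations from the full corpus, computes spectrum
    scores and recommendations, and explains positive associations with
    planted phytochemical tables.
    """
    ontology = generate_ontology(cfg)
    lexicon = generate_lexicon(cfg)
    records, truth = generate_corpus(cfg, ontology, lexicon)
    instances = label_from_truth(
        extract_instances(records, lexicon, ontology), truth
    )
    rng = Random(cfg.seed * 1_000_003 + 5)
    shuffled = list(instances)
    rng.shuffle(shuffled)
    n_train = int(round(train_fraction * len(shuffled)))
    train, test = shuffled[:n_train], shuffled[n_train:]
    model = train_svm(oversample(train, seed=cfg.seed), c=svm_c, seed=cfg.seed)
    test_metrics = evaluate(model.predict(test), [t.label for t in test])

    predictions = model.predict(instances)
    table = aggregate(zip(instances, predictions))
    report = SpectrumReport.compute(table, ontology)

    positives = AssociationTable(
        rows={k: v for k, v in table.rows.items() if k[2] == "positive"}
    )
    if positives.rows:
        (pairs, compounds), links, truth = generate_phytochem_tables(
            cfg, lexicon, ontology, positives, truth
        )
        explanation = explain(positives, pairs, links, compounds, ontology)
    else:
        explanation = ExplanationReport({}, {}, 0.0)
    return PipelineResult(
        instances=instances,
        model=model,
        test_metrics=test_metrics,
        table=table,
        report=report,
        explanation=explanation,
        truth=truth,
    )
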