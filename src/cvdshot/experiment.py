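"""Experiment protocols: repeats, consensus voting, confusion, ablation.

The canonical protocol classifies every image of a balanced manifest with
``k_per_class = 2`` references per class, repeats the whole pass ten times
with fresh reference draws, reports per-repeat accuracy as mean ± sd
(population sd, ddof 0), and aggregates the repeats with a consensus rule:
an image is called melanoma iff at least ``consensus_threshold`` (default 5)
of its repeats predicted melanoma.  The ablation harness keeps the query's
CVD simulation fixed and toggles whether references are simulated to match
or left non-simulated, sharing the base seed so reference *identities*
coincide across arms and only their coloring differs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from cvdshot.color_sim import CVDCondition, ValidationError
from cvdshot.dataset import DatasetManifest
from cvdshot.fewshot import (
    ConditionedImageStore,
    FewShotTask,
    classify,
    sample_references,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "ConsensusResult",
    "ConfusionCounts",
    "AblationResult",
    "run_experiment",
    "consensus",
    "confusion",
    "run_ablation",
    "result_summary",
]

_SCOREABLE = ("clean", "recovered")


@dataclass(frozen=True)
class ExperimentConfig:
    """Protocol parameters for one run."""

    condition_query: CVDCondition = CVDCondition.NONE
    condition_refs_mode: str = "matched"  # matched | non_simulated
    n_repeats: int = 10
    k_per_class: int = 2
    consensus_threshold: int = 5
    base_seed: int = 0
    backend_id: str = "mock-mean_color"
    color_model: str = "brettel"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "condition_query", CVDCondition.parse(self.condition_query)
        )
        if self.condition_refs_mode not in ("matched", "non_simulated"):
            raise ValidationError(
                "condition_refs_mode must be 'matched' or 'non_simulated'"
            )
        if self.n_repeats < 1 or self.k_per_class < 1:
            raise ValidationError("n_repeats and k_per_class must be >= 1")
        if not 1 <= self.consensus_threshold <= self.n_repeats:
            raise ValidationError("consensus_threshold must be in [1, n_repeats]")

    @property
    def condition_refs(self) -> CVDCondition:
        if self.condition_refs_mode == "matched":
            return self.condition_query
        return CVDCondition.NONE

    def digest(self) -> str:
        payload = {
            "condition_query": self.condition_query.value,
            "condition_refs_mode": self.condition_refs_mode,
            "n_repeats": self.n_repeats,
            "k_per_class": self.k_per_class,
            "base_seed": self.base_seed,
            "backend_id": self.backend_id,
            "color_model": self.color_model,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class ExperimentResult:
    """All prediction records of one run plus per-repeat accuracies.

    ``records`` follow the JSONL log schema (one dict per query x replicate:
    ids, conditions, reference ids, predicted label, explanation, parse
    status, digests).  Parse failures are excluded from accuracy
    denominators and counted in ``n_failed``.
    """

    config: ExperimentConfig
    records: List[dict]
    per_repeat_accuracy: List[float]
    n_failed: int = 0

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.per_repeat_accuracy))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.per_repeat_accuracy, ddof=0))


@dataclass
class ConsensusResult:
    per_image_votes: Dict[str, int]
    per_image_label: Dict[str, str]
    consensus_accuracy: float
    threshold: int
    excluded_ids: List[str] = field(default_factory=list)


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN with melanoma as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else float("nan")


@dataclass
class AblationResult:
    condition: CVDCondition
    matched: ExperimentResult
    non_simulated: ExperimentResult

    @property
    def accuracy_difference(self) -> float:
        """Matched-arm minus non-simulated-arm mean per-repeat accuracy."""
        return self.matched.mean_accuracy - self.non_simulated.mean_accuracy


def _load_completed(log_path: Path, config_digest: str) -> Dict[Tuple[str, int], dict]:
    done: Dict[Tuple[str, int], dict] = {}
    if log_path.exists():
        for line in log_path.read_text().splitlines():
            if not line.strip():
                continue
            record = json.loads(line)
            if record.get("config_digest") == config_digest:
                done[(record["query_id"], record["replicate"])] = record
    return done


def run_experiment(
    manifest: DatasetManifest,
    config: ExperimentConfig,
    backend: Callable,
    log_path: "str | Path | None" = None,
    store: Optional[ConditionedImageStore] = None,
) -> ExperimentResult:
    """Classify every manifest image ``n_repeats`` times.

    Replicate ``r`` samples references with seed ``base_seed + r``; the query
    is simulated under ``condition_query`` and references under the
    condition implied by ``condition_refs_mode``.  Completed
    (query, replicate) pairs found in ``log_path`` under the same config
    digest are skipped, making interrupted runs resumable; new records are
    appended as sorted-key JSON lines.
    """
    if store is None:
        store = ConditionedImageStore(manifest, model=config.color_model)
    digest = config.digest()
    done: Dict[Tuple[str, int], dict] = {}
    log_file = None
    if log_path is not None:
        log_path = Path(log_path)
        log_path.parent.mkdir(parents=True, exist_ok=True)
        done = _load_completed(log_path, digest)
        log_file = log_path.open("a")

    records: List[dict] = []
    per_repeat_accuracy: List[float] = []
    n_failed = 0
    try:
        for r in range(config.n_repeats):
            replicate_seed = config.base_seed + r
            correct = 0
            scoreable = 0
            for entry in manifest.entries:
                key = (entry.id, r)
                if key in done:
                    record = done[key]
                else:
                    refs = sample_references(
                        manifest, entry.id, config.k_per_class, replicate_seed
                    )
                    task = FewShotTask(
                        query=entry,
                        references=tuple((ref, ref.label) for ref in refs),
                        k_per_class=config.k_per_class,
                        condition_query=config.condition_query,
                        condition_refs=config.condition_refs,
                        replicate_index=r,
                        seed=replicate_seed,
                    )
                    prediction = classify(task, backend, store)
                    record = prediction.to_record()
                    record["config_digest"] = digest
                    if log_file is not None:
                        log_file.write(json.dumps(record, sort_keys=True) + "\n")
                records.append(record)
                if record["parse_status"] in _SCOREABLE:
                    scoreable += 1
                    if record["predicted_label"] == record["true_label"]:
                        correct += 1
                else:
                    n_failed += 1
            per_repeat_accuracy.append(
                correct / scoreable if scoreable else float("nan")
            )
    finally:
        if log_file is not None:
            log_file.close()
    return ExperimentResult(
        config=config,
        records=records,
        per_repeat_accuracy=per_repeat_accuracy,
        n_failed=n_failed,
    )


def consensus(
    source: "ExperimentResult | Sequence[dict]",
    threshold: Optional[int] = None,
) -> ConsensusResult:
    """Majority-vote aggregation: melanoma iff melanoma votes >= threshold.

    Votes are counted over parse-clean/recovered predictions only; images
    with no scoreable replicate are excluded and reported.
    """
    if isinstance(source, ExperimentResult):
        records = source.records
        if threshold is None:
            threshold = source.config.consensus_threshold
    else:
        records = list(source)
        if threshold is None:
            threshold = 5
    if threshold < 1:
        raise ValidationError("consensus threshold must be >= 1")
    votes: Dict[str, int] = {}
    scoreable_counts: Dict[str, int] = {}
    truth: Dict[str, str] = {}
    for record in records:
        qid = record["query_id"]
        truth[qid] = record["true_label"]
        votes.setdefault(qid, 0)
        scoreable_counts.setdefault(qid, 0)
        if record["parse_status"] in _SCOREABLE:
            scoreable_counts[qid] += 1
            if record["predicted_label"] == "melanoma":
                votes[qid] += 1
    excluded = sorted(qid for qid, n in scoreable_counts.items() if n == 0)
    if excluded:
        logger.warning("%d images had no scoreable replicate: %s",
                       len(excluded), excluded[:5])
    labels = {
        qid: ("melanoma" if votes[qid] >= threshold else "nevus")
        for qid in votes
        if qid not in excluded
    }
    n_correct = sum(1 for qid, lab in labels.items() if lab == truth[qid])
    accuracy = n_correct / len(labels) if labels else float("nan")
    return ConsensusResult(
        per_image_votes={qid: votes[qid] for qid in labels},
        per_image_label=labels,
        consensus_accuracy=accuracy,
        threshold=threshold,
        excluded_ids=excluded,
    )


def confusion(labels_true: Sequence[str], labels_pred: Sequence[str]) -> ConfusionCounts:
    """Tally TP/FP/TN/FN with melanoma as the positive class."""
    if len(labels_true) != len(labels_pred):
        raise ValidationError(
            f"label sequences differ in length: {len(labels_true)} vs {len(labels_pred)}"
        )
    tp = fp = tn = fn = 0
    for truth, pred in zip(labels_true, labels_pred):
        if truth == "melanoma":
            if pred == "melanoma":
                tp += 1
            else:
                fn += 1
        else:
            if pred == "melanoma":
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def run_ablation(
    manifest: DatasetManifest,
    condition: "str | CVDCondition",
    backend: Callable,
    config: Optional[ExperimentConfig] = None,
    log_dir: "str | Path | None" = None,
    store: Optional[ConditionedImageStore] = None,
) -> AblationResult:
    """Matched vs non-simulated reference arms for one CVD condition.

    Both arms share ``base_seed``, so each (query, replicate) pair samples
    the same reference identities; only the reference coloring differs.
    """
    condition = CVDCondition.parse(condition)
    if condition is CVDCondition.NONE:
        raise ValidationError("ablation requires a CVD condition other than 'none'")
    if config is None:
        config = ExperimentConfig()
    matched_cfg = replace(
        config, condition_query=condition, condition_refs_mode="matched"
    )
    unmatched_cfg = replace(
        config, condition_query=condition, condition_refs_mode="non_simulated"
    )
    if store is None:
        store = ConditionedImageStore(manifest, model=config.color_model)
    log_matched = log_unmatched = None
    if log_dir is not None:
        log_dir = Path(log_dir)
        log_dir.mkdir(parents=True, exist_ok=True)
        log_matched = log_dir / f"ablation_{condition.value}_matched.jsonl"
        log_unmatched = log_dir / f"ablation_{condition.value}_nonsim.jsonl"
    matched = run_experiment(manifest, matched_cfg, backend, log_matched, store)
    unmatched = run_experiment(manifest, unmatched_cfg, backend, log_unmatched, store)
    return AblationResult(condition=condition, matched=matched,
                          non_simulated=unmatched)


def result_summary(result: ExperimentResult,
                   threshold: Optional[int] = None) -> dict:
    """Per-run report: mean ± sd accuracy, consensus accuracy, confusion."""
    cons = consensus(result, threshold)
    truth = {r["query_id"]: r["true_label"] for r in result.records}
    ids = sorted(cons.per_image_label)
    counts = confusion([truth[i] for i in ids],
                       [cons.per_image_label[i] for i in ids])
    return {
        "condition_query": result.config.condition_query.value,
        "condition_refs_mode": result.config.condition_refs_mode,
        "n_repeats": result.config.n_repeats,
        "k_per_class": result.config.k_per_class,
        "mean_accuracy": result.mean_accuracy,
        "sd_accuracy": result.sd_accuracy,
        "per_repeat_accuracy": result.per_repeat_accuracy,
        "n_failed": result.n_failed,
        "consensus_accuracy": cons.consensus_accuracy,
        "consensus_threshold": cons.threshold,
        "confusion": {"tp": counts.tp, "fp": counts.fp,
                      "tn": counts.tn, "fn": counts.fn},
    }
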