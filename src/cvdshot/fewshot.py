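"""Few-shot in-context classification protocol.

One task = one query image plus ``k_per_class`` labeled reference images per
class, sampled leave-one-out from the dataset.  The composed prompt asks the
backend to pick the most similar reference and answer with a single class
word followed by an explanation of the color features it used.  Backends
are pluggable: any callable ``message -> BackendResponse`` satisfies the
contract (see :mod:`cvdshot.backends` for the deterministic mock and the
real-API adapter).
"""

from __future__ import annotations

import hashlib
import io
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from cvdshot.color_sim import ColorImage, CVDCondition, ValidationError, simulate_cvd
from cvdshot.dataset import LABELS, DatasetManifest, LabeledImage

logger = logging.getLogger(__name__)

__all__ = [
    "TEMPLATE_VERSION",
    "PROMPT_TEMPLATE",
    "FewShotTask",
    "PromptMessage",
    "Prediction",
    "ConditionedImageStore",
    "sample_references",
    "compose_prompt",
    "parse_response",
    "classify",
]

TEMPLATE_VERSION = "v1"

PROMPT_TEMPLATE = (
    "You are assisting with dermoscopic triage of pigmented skin lesions. "
    "You will see {n_refs} labeled reference images ({k} per class, "
    "melanoma first, then nevus) followed by one unlabeled query image. "
    "Compare the query with each reference, identify the most similar "
    "reference image, and use its label for your prediction. "
    "Answer with exactly one word first, 'melanoma' or 'nevus', followed by "
    "a brief explanation of the color features you relied on."
)


@dataclass(frozen=True)
class FewShotTask:
    """One query with its sampled references and the simulation conditions."""

    query: LabeledImage
    references: Tuple[Tuple[LabeledImage, str], ...]
    k_per_class: int
    condition_query: CVDCondition = CVDCondition.NONE
    condition_refs: CVDCondition = CVDCondition.NONE
    replicate_index: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_per_class < 1:
            raise ValidationError("k_per_class must be >= 1")
        if self.replicate_index < 0:
            raise ValidationError("replicate_index must be >= 0")
        ref_ids = [ref.id for ref, _ in self.references]
        if self.query.id in ref_ids:
            raise ValidationError("query image appears among its own references")
        counts = {label: 0 for label in LABELS}
        for ref, disclosed in self.references:
            counts[disclosed] += 1
        if any(count != self.k_per_class for count in counts.values()):
            raise ValidationError(
                f"references must contain exactly {self.k_per_class} per class, "
                f"got {counts}"
            )

    @property
    def reference_ids(self) -> List[str]:
        return [ref.id for ref, _ in self.references]


@dataclass(frozen=True)
class PromptMessage:
    """Ordered multimodal message: instruction text, labeled reference PNGs
    (melanoma first, then nevus, each in sampled order), query PNG last.

    ``query_id`` is metadata for offline test backends (the oracle backends
    need it); a real API adapter must not transmit it.
    """

    text: str
    references: Tuple[Tuple[str, bytes], ...]
    query_image: bytes
    template_version: str = TEMPLATE_VERSION
    query_id: Optional[str] = None

    @property
    def digest(self) -> str:
        """Hash of template version, text and all image bytes — the cache /
        resumability key for one request."""
        h = hashlib.sha256()
        h.update(self.template_version.encode())
        h.update(b"\x00")
        h.update(self.text.encode())
        for label, blob in self.references:
            h.update(b"\x00" + label.encode() + b"\x00")
            h.update(blob)
        h.update(b"\x00query\x00")
        h.update(self.query_image)
        return h.hexdigest()


@dataclass
class Prediction:
    """One backend answer for one task."""

    task: FewShotTask
    predicted_label: Optional[str]
    explanation: str
    parse_status: str  # clean | recovered | failed
    backend_id: str = ""
    request_digest: str = ""

    def to_record(self) -> dict:
        return {
            "query_id": self.task.query.id,
            "true_label": self.task.query.label,
            "replicate": self.task.replicate_index,
            "seed": self.task.seed,
            "condition_query": self.task.condition_query.value,
            "condition_refs": self.task.condition_refs.value,
            "reference_ids": self.task.reference_ids,
            "predicted_label": self.predicted_label,
            "explanation": self.explanation,
            "parse_status": self.parse_status,
            "backend_id": self.backend_id,
            "request_digest": self.request_digest,
        }


def sample_references(
    manifest: DatasetManifest,
    query_id: str,
    k_per_class: int,
    seed: int,
) -> List[LabeledImage]:
    """Sample ``k_per_class`` references per class, leave-one-out.

    Uniform without replacement, fully determined by (manifest order,
    query_id, k_per_class, seed).  The query id is mixed into the stream so
    that one replicate seed still gives every query an independent draw.
    Returned melanoma-first, each class in sampled order.
    """
    import zlib

    manifest.by_id(query_id)  # raises KeyError if absent
    rng = np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(query_id.encode())])
    )
    chosen: List[LabeledImage] = []
    for label in LABELS:
        candidates = [e for e in manifest.entries_for(label) if e.id != query_id]
        if len(candidates) < k_per_class:
            raise ValidationError(
                f"class {label!r} has only {len(candidates)} non-query images, "
                f"need {k_per_class}"
            )
        idx = rng.choice(len(candidates), size=k_per_class, replace=False)
        chosen.extend(candidates[i] for i in idx)
    return chosen


class ConditionedImageStore:
    """PNG bytes for (image id, CVD condition), simulated once and cached.

    When the requested condition equals the condition already applied to the
    file on disk, the raw file bytes are used; otherwise the image is
    simulated in memory and re-encoded as PNG.
    """

    def __init__(self, manifest: DatasetManifest, model: str = "brettel") -> None:
        self._manifest = manifest
        self._model = model
        self._cache: Dict[Tuple[str, CVDCondition], bytes] = {}

    def get(self, image_id: str, condition: "str | CVDCondition") -> bytes:
        condition = CVDCondition.parse(condition)
        key = (image_id, condition)
        if key not in self._cache:
            entry = self._manifest.by_id(image_id)
            if condition is entry.condition_applied:
                self._cache[key] = Path(entry.path).read_bytes()
            else:
                if entry.condition_applied is not CVDCondition.NONE:
                    raise ValidationError(
                        f"cannot re-simulate {image_id}: file already simulated "
                        f"under {entry.condition_applied.value}"
                    )
                image = ColorImage.open(entry.path)
                simulated = simulate_cvd(image, condition, model=self._model)
                buffer = io.BytesIO()
                data = np.rint(simulated.pixels * 255.0).astype(np.uint8)
                from PIL import Image as PILImage

                PILImage.fromarray(data, mode="RGB").save(buffer, format="PNG")
                self._cache[key] = buffer.getvalue()
        return self._cache[key]


def compose_prompt(task: FewShotTask, store: ConditionedImageStore) -> PromptMessage:
    """Render a task into the versioned multimodal message.

    References appear melanoma-first then nevus (each in sampled order) with
    disclosed labels; the query comes last with its label hidden.
    """
    ordered = sorted(
        task.references, key=lambda pair: (LABELS.index(pair[1]),)
    )
    text = PROMPT_TEMPLATE.format(
        n_refs=len(task.references), k=task.k_per_class
    )
    references = tuple(
        (disclosed, store.get(ref.id, task.condition_refs))
        for ref, disclosed in ordered
    )
    query_image = store.get(task.query.id, task.condition_query)
    return PromptMessage(
        text=text,
        references=references,
        query_image=query_image,
        query_id=task.query.id,
    )


_MELANOMA_WORDS = frozenset({"melanoma", "melanomas", "malignant", "malignancy"})
_NEVUS_WORDS = frozenset({"nevus", "nevi", "naevus", "benign"})


def parse_response(raw_text: str) -> Tuple[Optional[str], str, str]:
    """Extract (label, explanation, parse_status) from backend text.

    ``clean``: the very first word is a class keyword.  ``recovered``:
    exactly one class is mentioned somewhere else in the text.  ``failed``:
    no class keyword, or both classes mentioned without a leading answer.
    """
    import re

    tokens = re.findall(r"[a-zA-Z]+", raw_text.lower())
    if not tokens:
        return None, raw_text, "failed"
    first = tokens[0]
    if first in _MELANOMA_WORDS or first in _NEVUS_WORDS:
        label = "melanoma" if first in _MELANOMA_WORDS else "nevus"
        match = re.match(r"\s*[a-zA-Z]+[\s.,:;!-]*", raw_text)
        explanation = raw_text[match.end():].strip() if match else raw_text.strip()
        return label, explanation, "clean"
    mentions_mel = any(t in _MELANOMA_WORDS for t in tokens)
    mentions_nev = any(t in _NEVUS_WORDS for t in tokens)
    if mentions_mel ^ mentions_nev:
        return ("melanoma" if mentions_mel else "nevus"), raw_text.strip(), "recovered"
    return None, raw_text.strip(), "failed"


def classify(
    task: FewShotTask,
    backend: Callable,
    store: ConditionedImageStore,
    max_retries: int = 2,
    backoff_s: float = 0.1,
) -> Prediction:
    """Dispatch one task to a backend and parse its answer.

    Transport errors are retried with exponential backoff; when retries are
    exhausted a failed Prediction is returned (never an exception), so a
    long run survives flaky transports.
    """
    from cvdshot.backends import TransportError

    message = compose_prompt(task, store)
    response = None
    for attempt in range(max_retries + 1):
        try:
            response = backend(message)
            break
        except TransportError as exc:
            if attempt == max_retries:
                logger.error(
                    "backend transport failed for query %s replicate %d: %s",
                    task.query.id, task.replicate_index, exc,
                )
                return Prediction(
                    task=task,
                    predicted_label=None,
                    explanation=f"transport error: {exc}",
                    parse_status="failed",
                    backend_id=getattr(backend, "backend_id", "unknown"),
                    request_digest=message.digest,
                )
            time.sleep(backoff_s * (2.0 ** attempt))
    label, explanation, status = parse_response(response.raw_text)
    return Prediction(
        task=task,
        predicted_label=label,
        explanation=explanation,
        parse_status=status,
        backend_id=response.backend_id,
        request_digest=message.digest,
    )
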