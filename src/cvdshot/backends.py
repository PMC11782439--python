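"""Backends satisfying the few-shot contract: ``message -> BackendResponse``.

The deterministic :class:`MockBackend` literally implements the stated
protocol — identify the most similar reference image and use its label —
with a mean-color (or color-histogram) similarity, so the whole pipeline is
exercisable offline.  :class:`PerfectOracleBackend` and
:class:`LabelFlipBackend` are test instruments.  A thin adapter for
OpenAI-compatible vision endpoints is provided for real runs; it is never
used by the test suite.
"""

from __future__ import annotations

import base64
import hashlib
import io
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
from PIL import Image

from cvdshot.color_sim import _srgb_decode
from cvdshot.dataset import central_lesion_mask
from cvdshot.fewshot import PromptMessage

__all__ = [
    "TransportError",
    "BackendResponse",
    "MockBackend",
    "PerfectOracleBackend",
    "LabelFlipBackend",
    "OpenAIChatBackend",
    "get_backend",
]


class TransportError(RuntimeError):
    """A backend could not be reached; distinguishable from parse failures."""


@dataclass(frozen=True)
class BackendResponse:
    raw_text: str
    backend_id: str
    request_digest: str


def _decode_png(blob: bytes) -> np.ndarray:
    with Image.open(io.BytesIO(blob)) as im:
        return np.asarray(im.convert("RGB"), dtype=np.float64) / 255.0


def _hue_word(rgb: np.ndarray) -> str:
    """Map one sRGB triple to a coarse color word (red/pink/brown/blue/gray)."""
    r, g, b = float(rgb[0]), float(rgb[1]), float(rgb[2])
    mx, mn = max(r, g, b), min(r, g, b)
    v = mx
    s = 0.0 if mx <= 0 else (mx - mn) / mx
    if s < 0.12:
        return "gray"
    delta = mx - mn
    if mx == r:
        hue = (60.0 * ((g - b) / delta)) % 360.0
    elif mx == g:
        hue = 60.0 * ((b - r) / delta) + 120.0
    else:
        hue = 60.0 * ((r - g) / delta) + 240.0
    if hue < 25.0 or hue >= 330.0:
        if v < 0.55:
            return "brown"
        return "pink" if s < 0.5 else "red"
    if hue < 70.0:
        return "brown"
    if hue < 190.0:
        return "gray"
    if hue < 300.0:
        return "blue"
    return "pink"


class MockBackend:
    """Nearest-reference classifier over lesion-region color features.

    ``mode="mean_color"`` uses the Euclidean distance between mean linear-RGB
    colors of the central lesion region; ``mode="histogram"`` uses one minus
    the intersection of per-channel 8-bin sRGB histograms.  Ties go to the
    earliest reference in the message, i.e. to melanoma under the fixed
    melanoma-first presentation order.  The explanation names the query's
    modal hue word over lesion pixels, so explanation mining has signal.
    Fully deterministic; features are cached by image-bytes digest.
    """

    def __init__(self, mode: str = "mean_color", lesion_radius_frac: float = 0.35):
        if mode not in ("mean_color", "histogram"):
            raise ValueError(f"unknown mock similarity mode {mode!r}")
        self.mode = mode
        self.lesion_radius_frac = lesion_radius_frac
        self.backend_id = f"mock-{mode}"
        self._features: Dict[str, np.ndarray] = {}
        self._hues: Dict[str, str] = {}

    # -- feature extraction -------------------------------------------------
    def _lesion_pixels(self, blob: bytes) -> np.ndarray:
        pixels = _decode_png(blob)
        mask = central_lesion_mask(pixels.shape[:2], self.lesion_radius_frac)
        return pixels[mask]

    def _feature(self, blob: bytes) -> np.ndarray:
        key = hashlib.sha256(blob).hexdigest()
        if key not in self._features:
            region = self._lesion_pixels(blob)
            if self.mode == "mean_color":
                feat = _srgb_decode(region).mean(axis=0)
            else:
                bins = np.linspace(0.0, 1.0, 9)
                hists = [
                    np.histogram(region[:, c], bins=bins)[0] for c in range(3)
                ]
                feat = np.concatenate(hists).astype(np.float64)
                feat /= feat.sum()
            self._features[key] = feat
        return self._features[key]

    def _query_hue(self, blob: bytes) -> str:
        key = hashlib.sha256(blob).hexdigest()
        if key not in self._hues:
            region = self._lesion_pixels(blob)
            words = [_hue_word(px) for px in region[::7]]  # stride for speed
            order = ("red", "pink", "brown", "blue", "gray")
            counts = {w: 0 for w in order}
            for w in words:
                counts[w] += 1
            self._hues[key] = max(order, key=lambda w: counts[w])
        return self._hues[key]

    def _distance(self, a: np.ndarray, b: np.ndarray) -> float:
        if self.mode == "mean_color":
            return float(np.linalg.norm(a - b))
        return float(1.0 - np.minimum(a, b).sum())

    # -- contract ------------------------------------------------------------
    def __call__(self, message: PromptMessage) -> BackendResponse:
        if not message.references:
            raise ValueError("message carries no labeled references")
        query_feat = self._feature(message.query_image)
        distances = [
            self._distance(query_feat, self._feature(blob))
            for _, blob in message.references
        ]
        best = int(np.argmin(distances))  # first minimum wins ties
        label = message.references[best][0]
        hue = self._query_hue(message.query_image)
        text = (
            f"{label.capitalize()}. The query lesion appears predominantly "
            f"{hue}; it most closely resembles reference {best + 1}, which is "
            f"labeled {label}."
        )
        return BackendResponse(text, self.backend_id, message.digest)


class PerfectOracleBackend:
    """Answers with the query's true label (requires message.query_id)."""

    backend_id = "oracle-perfect"

    def __init__(self, labels_by_id: Dict[str, str]):
        self._labels = dict(labels_by_id)

    def __call__(self, message: PromptMessage) -> BackendResponse:
        label = self._labels[message.query_id]
        text = f"{label.capitalize()}. Answer read from the held-out label."
        return BackendResponse(text, self.backend_id, message.digest)


class LabelFlipBackend:
    """Adversarial control: always answers the wrong class."""

    backend_id = "oracle-flip"

    def __init__(self, labels_by_id: Dict[str, str]):
        self._labels = dict(labels_by_id)

    def __call__(self, message: PromptMessage) -> BackendResponse:
        true = self._labels[message.query_id]
        label = "nevus" if true == "melanoma" else "melanoma"
        text = f"{label.capitalize()}. Answer inverted from the held-out label."
        return BackendResponse(text, self.backend_id, message.digest)


class OpenAIChatBackend:
    """Adapter for OpenAI-compatible vision chat endpoints.

    Responses are cached on disk keyed by request digest so interrupted runs
    re-dispatch nothing.  Requires the optional ``openai`` extra; excluded
    from the offline test suite.
    """

    def __init__(self, model_id: str, cache_dir: Optional[str] = None, **client_kwargs):
        try:
            from openai import OpenAI
        except ImportError as exc:  # pragma: no cover - optional extra
            raise ImportError(
                "the real-API backend needs the 'openai' extra: "
                "pip install cvdshot[api]"
            ) from exc
        self._client = OpenAI(**client_kwargs)
        self.backend_id = model_id
        self._cache_dir = cache_dir

    def __call__(self, message: PromptMessage) -> BackendResponse:  # pragma: no cover
        import pathlib

        if self._cache_dir:
            cached = pathlib.Path(self._cache_dir) / f"{message.digest}.txt"
            if cached.exists():
                return BackendResponse(cached.read_text(), self.backend_id,
                                       message.digest)
        content = [{"type": "text", "text": message.text}]
        for label, blob in message.references:
            content.append({"type": "text", "text": f"Reference ({label}):"})
            content.append(
                {"type": "image_url", "image_url": {
                    "url": "data:image/png;base64,"
                           + base64.b64encode(blob).decode()}}
            )
        content.append({"type": "text", "text": "Query image:"})
        content.append(
            {"type": "image_url", "image_url": {
                "url": "data:image/png;base64,"
                       + base64.b64encode(message.query_image).decode()}}
        )
        try:
            completion = self._client.chat.completions.create(
                model=self.backend_id,
                messages=[{"role": "user", "content": content}],
            )
        except Exception as exc:
            raise TransportError(str(exc)) from exc
        text = completion.choices[0].message.content or ""
        if self._cache_dir:
            pathlib.Path(self._cache_dir).mkdir(parents=True, exist_ok=True)
            (pathlib.Path(self._cache_dir) / f"{message.digest}.txt").write_text(text)
        return BackendResponse(text, self.backend_id, message.digest)


def get_backend(spec: str, labels_by_id: Optional[Dict[str, str]] = None):
    """Resolve a CLI backend spec: ``mock``, ``mock:histogram``, ``oracle``,
    ``flip``, or ``api:<model-id>``."""
    if spec == "mock":
        return MockBackend()
    if spec.startswith("mock:"):
        return MockBackend(mode=spec.split(":", 1)[1])
    if spec == "oracle":
        return PerfectOracleBackend(labels_by_id or {})
    if spec == "flip":
        return LabelFlipBackend(labels_by_id or {})
    if spec.startswith("api:"):
        return OpenAIChatBackend(spec.split(":", 1)[1])
    raise ValueError(f"unknown backend spec {spec!r}")
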