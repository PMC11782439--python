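"""Unit tests for reference sampling, prompt composition, parsing, and the
deterministic mock backend."""

import dataclasses

import numpy as np
import pytest

from cvdshot.backends import (
    BackendResponse,
    MockBackend,
    TransportError,
    _decode_png,
    _hue_word,
)
from cvdshot.color_sim import CVDCondition, ValidationError, _srgb_decode
from cvdshot.dataset import apply_condition, central_lesion_mask
from cvdshot.fewshot import (
    ConditionedImageStore,
    FewShotTask,
    PromptMessage,
    classify,
    compose_prompt,
    parse_response,
    sample_references,
)


def _make_task(manifest, query_id, k=2, seed=0, **kwargs):
    refs = sample_references(manifest, query_id, k, seed)
    return FewShotTask(
        query=manifest.by_id(query_id),
        references=tuple((r, r.label) for r in refs),
        k_per_class=k,
        seed=seed,
        **kwargs,
    )


class TestSampling:
    def test_leave_one_out_and_balance(self, small_manifest):
        refs = sample_references(small_manifest, "m_000", 2, seed=42)
        assert len(refs) == 4
        labels = [r.label for r in refs]
        assert labels == ["melanoma", "melanoma", "nevus", "nevus"]
        assert "m_000" not in {r.id for r in refs}

    def test_deterministic_given_seed(self, small_manifest):
        a = sample_references(small_manifest, "n_003", 2, seed=9)
        b = sample_references(small_manifest, "n_003", 2, seed=9)
        assert [r.id for r in a] == [r.id for r in b]

    def test_different_seeds_differ(self, small_manifest):
        draws = {
            tuple(r.id for r in sample_references(small_manifest, "m_001", 2, s))
            for s in range(20)
        }
        assert len(draws) > 1

    def test_insufficient_class_members(self, small_manifest):
        # 6 melanomas minus the query leaves only 5
        with pytest.raises(ValidationError, match="melanoma"):
            sample_references(small_manifest, "m_000", 6, seed=0)

    def test_unknown_query(self, small_manifest):
        with pytest.raises(KeyError):
            sample_references(small_manifest, "ghost", 2, seed=0)


class TestPrompt:
    def test_message_structure(self, small_manifest):
        store = ConditionedImageStore(small_manifest)
        task = _make_task(small_manifest, "m_000")
        message = compose_prompt(task, store)
        assert [label for label, _ in message.references] == [
            "melanoma", "melanoma", "nevus", "nevus"]
        assert message.query_image  # query present, last and unlabeled
        assert "melanoma" in message.text and "nevus" in message.text

    def test_replicate_index_does_not_change_text(self, small_manifest):
        store = ConditionedImageStore(small_manifest)
        a = compose_prompt(_make_task(small_manifest, "m_000", replicate_index=0),
                           store)
        b = compose_prompt(_make_task(small_manifest, "m_000", replicate_index=3),
                           store)
        assert a.text == b.text

    def test_template_version_changes_digest(self, small_manifest):
        store = ConditionedImageStore(small_manifest)
        message = compose_prompt(_make_task(small_manifest, "m_000"), store)
        bumped = dataclasses.replace(message, template_version="v2")
        assert message.digest != bumped.digest

    def test_task_rejects_query_among_references(self, small_manifest):
        query = small_manifest.by_id("m_000")
        other = small_manifest.by_id("n_000")
        with pytest.raises(ValidationError, match="own references"):
            FewShotTask(query=query,
                        references=((query, "melanoma"), (other, "nevus")),
                        k_per_class=1)

    def test_task_rejects_class_imbalance(self, small_manifest):
        query = small_manifest.by_id("m_000")
        refs = tuple(
            (small_manifest.by_id(i), "melanoma") for i in ("m_001", "m_002")
        )
        with pytest.raises(ValidationError, match="per class"):
            FewShotTask(query=query, references=refs, k_per_class=1)


class TestParsing:
    @pytest.mark.parametrize("raw,label,status", [
        ("Melanoma. The lesion shows irregular red streaks.",
         "melanoma", "clean"),
        ("nevus: uniform pink coloration", "nevus", "clean"),
        ("This appears benign (nevus), given uniform pink coloration.",
         "nevus", "recovered"),
        ("Likely a melanoma given the blue-gray veil.", "melanoma", "recovered"),
        ("Cannot determine.", None, "failed"),
        ("Could be melanoma or a benign nevus.", None, "failed"),
        ("", None, "failed"),
    ])
    def test_parse_cases(self, raw, label, status):
        parsed_label, explanation, parsed_status = parse_response(raw)
        assert parsed_label == label
        assert parsed_status == status
        if status == "clean":
            assert not explanation.lower().startswith(("melanoma", "nevus"))

    def test_clean_explanation_is_remainder(self):
        _, explanation, _ = parse_response("Melanoma. Irregular red streaks.")
        assert explanation == "Irregular red streaks."


class TestClassify:
    def test_retries_transient_transport_errors(self, small_manifest):
        store = ConditionedImageStore(small_manifest)
        task = _make_task(small_manifest, "m_000")
        calls = {"n": 0}

        def flaky(message):
            calls["n"] += 1
            if calls["n"] < 3:
                raise TransportError("connection reset")
            return BackendResponse("Melanoma. Recovered after retry.",
                                   "flaky", message.digest)

        prediction = classify(task, flaky, store, max_retries=3, backoff_s=0.0)
        assert prediction.predicted_label == "melanoma"
        assert calls["n"] == 3

    def test_exhausted_retries_fail_softly(self, small_manifest):
        store = ConditionedImageStore(small_manifest)
        task = _make_task(small_manifest, "m_000")

        def dead(message):
            raise TransportError("gateway down")

        prediction = classify(task, dead, store, max_retries=1, backoff_s=0.0)
        assert prediction.parse_status == "failed"
        assert prediction.predicted_label is None


class TestMockBackend:
    def test_identical_query_wins(self, small_manifest):
        store = ConditionedImageStore(small_manifest)
        blob = store.get("m_001", "none")
        message = PromptMessage(
            text="t",
            references=(("melanoma", blob),
                        ("nevus", store.get("n_001", "none"))),
            query_image=blob,
        )
        response = MockBackend()(message)
        assert response.raw_text.startswith("Melanoma")

    def test_equidistant_tie_goes_to_melanoma(self, small_manifest):
        store = ConditionedImageStore(small_manifest)
        blob = store.get("m_001", "none")
        message = PromptMessage(
            text="t",
            references=(("melanoma", blob), ("nevus", blob)),
            query_image=store.get("n_002", "none"),
        )
        response = MockBackend()(message)
        assert response.raw_text.startswith("Melanoma")

    @pytest.mark.parametrize("mode", ["mean_color", "histogram"])
    def test_prediction_matches_exhaustive_distance_table(
            self, small_manifest, mode):
        """Brute-force recomputation of every query-reference distance."""
        store = ConditionedImageStore(small_manifest)
        backend = MockBackend(mode=mode)
        task = _make_task(small_manifest, "m_000", seed=7)
        message = compose_prompt(task, store)
        response = backend(message)

        def feature(blob):
            pixels = _decode_png(blob)
            region = pixels[central_lesion_mask(pixels.shape[:2], 0.35)]
            if mode == "mean_color":
                return _srgb_decode(region).mean(axis=0)
            bins = np.linspace(0.0, 1.0, 9)
            h = np.concatenate(
                [np.histogram(region[:, c], bins=bins)[0] for c in range(3)]
            ).astype(float)
            return h / h.sum()

        q = feature(message.query_image)
        table = []
        for label, blob in message.references:
            f = feature(blob)
            if mode == "mean_color":
                table.append((float(np.linalg.norm(q - f)), label))
            else:
                table.append((float(1.0 - np.minimum(q, f).sum()), label))
        expected_label = min(enumerate(table), key=lambda it: (it[1][0], it[0]))[1][1]
        assert response.raw_text.lower().startswith(expected_label)

    def test_pure_function_of_bytes(self, small_manifest):
        store = ConditionedImageStore(small_manifest)
        task = _make_task(small_manifest, "n_000", seed=3)
        backend = MockBackend()
        first = classify(task, backend, store)
        second = classify(task, MockBackend(), store)
        assert first.to_record() == second.to_record()

    def test_matched_condition_pathway_consistency(self, small_manifest, tmp_path):
        """Pre-simulating images on disk or simulating in memory must give
        the mock identical bytes, hence identical predictions."""
        condition = CVDCondition.TRITANOPIA
        pre = apply_condition(small_manifest, condition, tmp_path / "trit")
        store_raw = ConditionedImageStore(small_manifest)
        store_pre = ConditionedImageStore(pre)
        backend = MockBackend()
        for qid in ("m_000", "n_004"):
            task_raw = _make_task(
                small_manifest, qid, seed=5,
                condition_query=condition, condition_refs=condition)
            task_pre = _make_task(
                pre, qid, seed=5,
                condition_query=condition, condition_refs=condition)
            a = classify(task_raw, backend, store_raw)
            b = classify(task_pre, backend, store_pre)
            assert a.predicted_label == b.predicted_label
            assert a.request_digest == b.request_digest

    def test_hue_words(self):
        assert _hue_word(np.array([0.70, 0.15, 0.18])) == "red"
        assert _hue_word(np.array([0.88, 0.66, 0.64])) == "pink"
        assert _hue_word(np.array([0.45, 0.20, 0.18])) == "brown"
        assert _hue_word(np.array([0.40, 0.45, 0.60])) == "blue"
        assert _hue_word(np.array([0.5, 0.5, 0.5])) == "gray"
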