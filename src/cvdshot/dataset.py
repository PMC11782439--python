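"""Labeled dermoscopic image collections and synthetic fixtures.

A dataset is a directory with one subdirectory per class label
(``root/melanoma/*.png``, ``root/nevus/*.png``) plus an optional JSON
manifest.  The fixture generator draws two-class "dermoscopic-like" images —
an elliptical lesion over a skin-tone background — whose class-conditional
color statistics are separable: melanomas are multi-hued (red, dark brown,
black, blue-gray patches) with irregular borders, nevi are uniform light
brown to pink with smooth borders.  That contrast is what gives a
color-based classifier signal, and what dichromacy simulation perturbs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from cvdshot.color_sim import ColorImage, CVDCondition, ValidationError, simulate_cvd

logger = logging.getLogger(__name__)

__all__ = [
    "LABELS",
    "LabeledImage",
    "DatasetManifest",
    "FixtureSpec",
    "load_manifest",
    "generate_fixtures",
    "apply_condition",
    "central_lesion_mask",
    "mean_lesion_redness",
]

#: The closed two-class label set, in fixed (positive-class-first) order.
LABELS: Tuple[str, str] = ("melanoma", "nevus")

MANIFEST_NAME = "manifest.json"


@dataclass(frozen=True)
class LabeledImage:
    """One image of the dataset: id (file basename), label, location, and
    which CVD condition its pixels have already been simulated under."""

    id: str
    label: str
    path: Path
    condition_applied: CVDCondition = CVDCondition.NONE

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValidationError(
                f"label {self.label!r} not in allowed set {list(LABELS)}"
            )


@dataclass
class DatasetManifest:
    """Deterministically ordered list of labeled images."""

    entries: List[LabeledImage]
    root: Optional[Path] = None

    @property
    def class_counts(self) -> Dict[str, int]:
        counts = {label: 0 for label in LABELS}
        for entry in self.entries:
            counts[entry.label] += 1
        return counts

    @property
    def balanced(self) -> bool:
        return len(set(self.class_counts.values())) == 1

    def __len__(self) -> int:
        return len(self.entries)

    def ids(self) -> List[str]:
        return [entry.id for entry in self.entries]

    def by_id(self, image_id: str) -> LabeledImage:
        for entry in self.entries:
            if entry.id == image_id:
                return entry
        raise KeyError(image_id)

    def labels_by_id(self) -> Dict[str, str]:
        return {entry.id: entry.label for entry in self.entries}

    def entries_for(self, label: str) -> List[LabeledImage]:
        return [entry for entry in self.entries if entry.label == label]

    def to_dict(self) -> dict:
        root = self.root
        entries = []
        for entry in self.entries:
            path = entry.path
            if root is not None:
                try:
                    path = path.relative_to(root)
                except ValueError:
                    pass
            entries.append(
                {
                    "id": entry.id,
                    "label": entry.label,
                    "path": str(path),
                    "condition": entry.condition_applied.value,
                }
            )
        return {"entries": entries, "class_counts": self.class_counts}

    def save(self, path: "str | Path") -> None:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_dict(cls, payload: dict, root: Optional[Path] = None) -> "DatasetManifest":
        entries = [
            LabeledImage(
                id=item["id"],
                label=item["label"],
                path=(root / item["path"]) if root is not None else Path(item["path"]),
                condition_applied=CVDCondition.parse(item.get("condition", "none")),
            )
            for item in payload["entries"]
        ]
        return cls(entries=entries, root=root)

    @classmethod
    def load(cls, path: "str | Path") -> "DatasetManifest":
        path = Path(path)
        payload = json.loads(path.read_text())
        return cls.from_dict(payload, root=path.parent)


_IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg")


def load_manifest(root_dir: "str | Path") -> DatasetManifest:
    """Scan ``root/<label>/`` subdirectories into a manifest.

    Ordering is lexicographic by image id, so downstream sampling is fully
    reproducible from (manifest, seed).  Unknown class subdirectories and
    empty classes are errors.
    """
    root = Path(root_dir)
    if not root.is_dir():
        raise ValidationError(f"dataset root {root} is not a directory")
    subdirs = sorted(p.name for p in root.iterdir() if p.is_dir())
    unknown = [name for name in subdirs if name not in LABELS]
    if unknown:
        raise ValidationError(
            f"unknown class directories {unknown}; allowed labels are {list(LABELS)}"
        )
    entries: List[LabeledImage] = []
    for label in LABELS:
        class_dir = root / label
        files = (
            sorted(
                p for p in class_dir.iterdir()
                if p.is_file() and p.suffix.lower() in _IMAGE_SUFFIXES
            )
            if class_dir.is_dir()
            else []
        )
        if not files:
            raise ValidationError(f"class {label!r} has no images under {root}")
        for path in files:
            entries.append(LabeledImage(id=path.stem, label=label, path=path))
    entries.sort(key=lambda e: e.id)
    ids = [e.id for e in entries]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate image ids across classes")
    return DatasetManifest(entries=entries, root=root)


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------


@dataclass
class FixtureSpec:
    """Parameters of the synthetic two-class lesion image generator.

    Defaults draw 50 images per class at 128x128 px — a balanced n=100
    design — with melanoma lesions mixing red / dark-brown / black /
    blue-gray patches (Dirichlet mixing weights) and nevi filled with a
    single color interpolated between light brown and pink.  ``noise_sd``
    is the per-channel additive Gaussian sd in sRGB units.
    """

    n_per_class: int = 50
    image_size: Tuple[int, int] = (128, 128)
    melanoma_palette: Dict[str, Tuple[float, float, float]] = field(
        default_factory=lambda: {
            "red": (0.70, 0.15, 0.18),
            "dark_brown": (0.45, 0.20, 0.18),
            "black": (0.15, 0.10, 0.10),
            "blue_gray": (0.40, 0.45, 0.55),
        }
    )
    melanoma_weight_alpha: Tuple[float, ...] = (4.0, 3.0, 2.0, 1.0)
    nevus_palette: Dict[str, Tuple[float, float, float]] = field(
        default_factory=lambda: {
            "light_brown": (0.78, 0.58, 0.50),
            "pink": (0.88, 0.64, 0.64),
        }
    )
    background_skin_tone: Tuple[float, float, float] = (0.86, 0.70, 0.62)
    background_jitter: float = 0.04
    noise_sd: float = 0.02
    seed: int = 20240427
    redness_margin: float = 0.04

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValidationError("n_per_class must be >= 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if len(self.melanoma_weight_alpha) != len(self.melanoma_palette):
            raise ValidationError("one Dirichlet alpha per melanoma palette entry")


def _lesion_geometry(rng: np.random.Generator, height: int, width: int, irregular: bool):
    """Ellipse center/radii plus a radial boundary perturbation r(phi)."""
    cy = height / 2.0 * (1.0 + rng.uniform(-0.12, 0.12))
    cx = width / 2.0 * (1.0 + rng.uniform(-0.12, 0.12))
    base = min(height, width)
    ry = rng.uniform(0.24, 0.34) * base
    rx = rng.uniform(0.24, 0.34) * base
    if irregular:
        amps = rng.normal(0.0, 0.05, size=4)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=4)
    else:
        amps = np.zeros(4)
        phases = np.zeros(4)

    yy, xx = np.mgrid[0:height, 0:width]
    dy = (yy - cy) / ry
    dx = (xx - cx) / rx
    radius = np.hypot(dy, dx)
    phi = np.arctan2(dy, dx)
    boundary = np.ones_like(phi)
    for k, (a, p) in enumerate(zip(amps, phases), start=2):
        boundary = boundary + a * np.sin(k * phi + p)
    boundary = np.clip(boundary, 0.6, 1.4)
    # soft antialiased edge, ~1.5 px wide
    aa = 1.5 / min(rx, ry)
    alpha = np.clip((boundary - radius) / aa + 0.5, 0.0, 1.0)
    return alpha, (cy, cx)


def _melanoma_fill(rng: np.random.Generator, spec: FixtureSpec,
                   height: int, width: int, center: Tuple[float, float]) -> np.ndarray:
    """Blotchy multi-component fill: Voronoi cells over random seed points,
    each cell colored by a palette component drawn with Dirichlet weights."""
    colors = np.array(list(spec.melanoma_palette.values()))
    weights = rng.dirichlet(spec.melanoma_weight_alpha)
    n_sites = 6
    sites_y = center[0] + rng.normal(0.0, 0.18 * height, size=n_sites)
    sites_x = center[1] + rng.normal(0.0, 0.18 * width, size=n_sites)
    site_component = rng.choice(len(colors), size=n_sites, p=weights)
    yy, xx = np.mgrid[0:height, 0:width]
    d2 = (yy[..., None] - sites_y) ** 2 + (xx[..., None] - sites_x) ** 2
    nearest = np.argmin(d2, axis=-1)
    fill = colors[site_component[nearest]]
    fill = fill + rng.normal(0.0, 0.015, size=fill.shape)
    return fill


def _nevus_fill(rng: np.random.Generator, spec: FixtureSpec,
                height: int, width: int, center: Tuple[float, float]) -> np.ndarray:
    """Uniform fill interpolated between the two nevus palette poles, with a
    mild radial darkening toward the rim."""
    poles = np.array(list(spec.nevus_palette.values()))
    t = rng.uniform(0.0, 1.0)
    base = (1.0 - t) * poles[0] + t * poles[1] + rng.normal(0.0, 0.01, size=3)
    yy, xx = np.mgrid[0:height, 0:width]
    r = np.hypot((yy - center[0]) / height, (xx - center[1]) / width)
    shade = 1.0 - 0.15 * np.clip(r / 0.4, 0.0, 1.0) ** 2
    return base[None, None, :] * shade[..., None]


def _render_fixture(spec: FixtureSpec, label: str, rng: np.random.Generator) -> np.ndarray:
    height, width = spec.image_size
    background = np.asarray(spec.background_skin_tone) + rng.uniform(
        -spec.background_jitter, spec.background_jitter, size=3
    )
    image = np.broadcast_to(background, (height, width, 3)).copy()
    alpha, center = _lesion_geometry(rng, height, width, irregular=(label == "melanoma"))
    if label == "melanoma":
        fill = _melanoma_fill(rng, spec, height, width, center)
    else:
        fill = _nevus_fill(rng, spec, height, width, center)
    image = image * (1.0 - alpha[..., None]) + fill * alpha[..., None]
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    return np.clip(image, 0.0, 1.0)


_ID_PREFIX = {"melanoma": "m", "nevus": "n"}


def generate_fixtures(spec: FixtureSpec, out_dir: "str | Path") -> DatasetManifest:
    """Write ``2 * n_per_class`` synthetic PNGs under ``out_dir/<label>/``.

    Generation is a pure function of (spec, seed): each image draws from a
    dedicated child stream ``SeedSequence([seed, class_index, image_index])``,
    so identical inputs produce bit-identical files.  A manifest is written
    alongside and returned.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries: List[LabeledImage] = []
    for class_index, label in enumerate(LABELS):
        class_dir = out / label
        class_dir.mkdir(parents=True, exist_ok=True)
        for i in range(spec.n_per_class):
            rng = np.random.default_rng(
                np.random.SeedSequence([spec.seed, class_index, i])
            )
            pixels = _render_fixture(spec, label, rng)
            image_id = f"{_ID_PREFIX[label]}_{i:03d}"
            path = class_dir / f"{image_id}.png"
            ColorImage(pixels, "srgb").save(path)
            entries.append(LabeledImage(id=image_id, label=label, path=path))
    entries.sort(key=lambda e: e.id)
    manifest = DatasetManifest(entries=entries, root=out)
    manifest.save(out / MANIFEST_NAME)
    redness = mean_lesion_redness(manifest)
    gap = redness["melanoma"] - redness["nevus"]
    if gap <= spec.redness_margin:
        logger.warning(
            "class redness separation %.4f below configured margin %.4f",
            gap, spec.redness_margin,
        )
    return manifest


def apply_condition(
    manifest: DatasetManifest,
    condition: "str | CVDCondition",
    out_dir: "str | Path",
    model: str = "brettel",
) -> DatasetManifest:
    """Simulate every manifest image under one CVD condition.

    Ids, labels and counts are preserved; per-file failures are logged and
    the batch continues.  ``none`` writes unmodified copies.
    """
    condition = CVDCondition.parse(condition)
    out = Path(out_dir)
    entries: List[LabeledImage] = []
    for entry in manifest.entries:
        class_dir = out / entry.label
        class_dir.mkdir(parents=True, exist_ok=True)
        target = class_dir / f"{entry.id}.png"
        try:
            image = ColorImage.open(entry.path)
            simulate_cvd(image, condition, model=model).save(target)
        except (OSError, ValidationError) as exc:
            logger.error("failed to simulate %s: %s", entry.path, exc)
            continue
        entries.append(
            LabeledImage(id=entry.id, label=entry.label, path=target,
                         condition_applied=condition)
        )
    result = DatasetManifest(entries=entries, root=out)
    result.save(out / MANIFEST_NAME)
    return result


def central_lesion_mask(shape: Tuple[int, int], radius_frac: float = 0.35) -> np.ndarray:
    """Boolean disk around the image center.

    Fixtures place the lesion near the center, so this mask is the
    operational "lesion region" used when no segmentation is available
    (fixture statistics, the mock backend's color features).
    """
    height, width = shape
    yy, xx = np.mgrid[0:height, 0:width]
    r = np.hypot(yy - (height - 1) / 2.0, xx - (width - 1) / 2.0)
    return r <= radius_frac * min(height, width)


def mean_lesion_redness(manifest: DatasetManifest) -> Dict[str, float]:
    """Per-class mean red dominance, R - (G+B)/2, over the lesion region."""
    sums = {label: [] for label in LABELS}
    for entry in manifest.entries:
        pixels = ColorImage.open(entry.path).pixels
        mask = central_lesion_mask(pixels.shape[:2])
        region = pixels[mask]
        sums[entry.label].append(
            float(np.mean(region[:, 0] - 0.5 * (region[:, 1] + region[:, 2])))
        )
    return {label: float(np.mean(values)) for label, values in sums.items()}
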