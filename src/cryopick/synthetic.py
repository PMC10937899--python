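"""Synthetic micrograph scenes with exact ground truth.

The generator composes the gross features a picker has to cope with in
real cryo-EM data — roughly round low-contrast particles, additive noise,
soft ice blobs, a carbon-edge intensity ramp — without attempting
physical image formation (no CTF, no 3-D projection).  Particles are
rendered dark against a brighter background, the usual cryo-EM contrast.

Everything is driven by one ``numpy`` Generator seeded from
``SceneSpec.seed``: the same spec reproduces a bit-identical scene.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import expit

from cryopick.io import (
    Micrograph,
    ParticleAnnotation,
    export_coco,
    import_coco,
    load_coco,
    read_mrc,
    save_coco,
    write_coord_table,
    write_mrc,
)

__all__ = [
    "SceneSpec",
    "InfeasiblePackingError",
    "simulate_scene",
    "scene_to_dataset",
    "dataset_from_dir",
]


class InfeasiblePackingError(RuntimeError):
    """Raised when rejection sampling cannot place all particles."""


@dataclass
class SceneSpec:
    """Parameters of one synthetic micrograph.

    ``particle_diameter`` may be a single value or an inclusive
    ``(low, high)`` range sampled per particle.
    """

    image_height: int = 256
    image_width: int = 256
    particle_count: int = 20
    particle_diameter: float | tuple[float, float] = 16.0
    particle_shape: str = "disk"  # disk | annulus | ellipse
    min_center_separation: float = 18.0
    noise_sigma: float = 0.3
    ice_patch_count: int = 1
    carbon_edge: bool = False
    seed: int = 0
    background: float = 1.0
    particle_contrast: float = 0.45  # intensity drop at particle centers
    dark_particles: bool = True
    shot_noise: bool = False
    name: str | None = None

    _MAX_ATTEMPTS = 10_000  # rejection-sampling cap per particle

    def __post_init__(self):
        if self.particle_shape not in ("disk", "annulus", "ellipse"):
            raise ValueError(f"unknown particle_shape {self.particle_shape!r}")
        if self.particle_count < 0:
            raise ValueError("particle_count must be >= 0")

    def diameter_range(self) -> tuple[float, float]:
        d = self.particle_diameter
        if np.isscalar(d):
            return float(d), float(d)  # type: ignore[arg-type]
        lo, hi = d  # type: ignore[misc]
        return float(lo), float(hi)


def _sample_centers(spec: SceneSpec, rng: np.random.Generator):
    """Rejection-sample particle centers honoring margins and separation."""
    lo, hi = spec.diameter_range()
    centers: list[tuple[float, float]] = []
    diams: list[float] = []
    for k in range(spec.particle_count):
        d = float(rng.uniform(lo, hi)) if hi > lo else lo
        margin = d / 2.0
        placed = False
        for _ in range(SceneSpec._MAX_ATTEMPTS):
            x = rng.uniform(margin, spec.image_width - margin)
            y = rng.uniform(margin, spec.image_height - margin)
            ok = all(
                (x - cx) ** 2 + (y - cy) ** 2 >= spec.min_center_separation**2
                for cx, cy in centers
            )
            if ok:
                centers.append((x, y))
                diams.append(d)
                placed = True
                break
        if not placed:
            raise InfeasiblePackingError(
                f"could not place particle {k + 1}/{spec.particle_count} with "
                f"min_center_separation={spec.min_center_separation} in a "
                f"{spec.image_height}x{spec.image_width} image after "
                f"{SceneSpec._MAX_ATTEMPTS} attempts"
            )
    return centers, diams


def _render_particles(spec: SceneSpec, centers, diams, rng) -> np.ndarray:
    h, w = spec.image_height, spec.image_width
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)
    img = np.zeros((h, w), dtype=np.float32)
    edge = 1.0  # soft-edge width in pixels
    for (cx, cy), d in zip(centers, diams):
        r = d / 2.0
        if spec.particle_shape == "ellipse":
            ratio = rng.uniform(0.6, 1.0)
            theta = rng.uniform(0, np.pi)
            ct, st = np.cos(theta), np.sin(theta)
            u = (xx - cx) * ct + (yy - cy) * st
            v = -(xx - cx) * st + (yy - cy) * ct
            rad = np.sqrt(u**2 + (v / ratio) ** 2)
        else:
            rad = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
        profile = expit(-(rad - r) / edge)
        if spec.particle_shape == "annulus":
            profile = profile - expit(-(rad - 0.55 * r) / edge)
        img += spec.particle_contrast * profile.astype(np.float32)
    return img


def _render_artifacts(spec: SceneSpec, rng) -> np.ndarray:
    h, w = spec.image_height, spec.image_width
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)
    art = np.zeros((h, w), dtype=np.float32)
    for _ in range(spec.ice_patch_count):
        cx = rng.uniform(0, w)
        cy = rng.uniform(0, h)
        radius = rng.uniform(0.12, 0.25) * min(h, w)
        amp = rng.uniform(0.1, 0.25) * (1 if rng.uniform() < 0.3 else -1)
        art += amp * np.exp(
            -((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * radius**2)
        ).astype(np.float32)
    if spec.carbon_edge:
        theta = rng.uniform(0, 2 * np.pi)
        offset = rng.uniform(0.25, 0.75) * min(h, w)
        dist = (xx - w / 2) * np.cos(theta) + (yy - h / 2) * np.sin(theta) + offset - min(h, w) / 2
        art += (-0.3 * expit(dist / 5.0)).astype(np.float32)
    return art


def simulate_scene(spec: SceneSpec, return_clean: bool = False):
    """Render one scene.

    Returns ``(micrograph, annotations)``, or with ``return_clean=True``
    additionally the noise-free composite (useful as a denoising oracle).
    """
    rng = np.random.default_rng(spec.seed)
    centers, diams = _sample_centers(spec, rng)
    sign = -1.0 if spec.dark_particles else 1.0
    clean = (
        spec.background
        + sign * _render_particles(spec, centers, diams, rng)
        + _render_artifacts(spec, rng)
    ).astype(np.float32)
    noisy = clean
    if spec.shot_noise:
        scale = 50.0  # pseudo electron counts per unit intensity
        noisy = rng.poisson(np.clip(noisy, 0, None) * scale).astype(np.float32) / scale
    if spec.noise_sigma > 0:
        noisy = noisy + rng.normal(0.0, spec.noise_sigma, size=clean.shape).astype(
            np.float32
        )
    name = spec.name or f"scene{spec.seed:06d}"
    mic = Micrograph(pixels=noisy.astype(np.float32), name=name)
    anns = [
        ParticleAnnotation(
            center_x=cx, center_y=cy, diameter=d, image_ref=name, particle_id=i + 1
        )
        for i, ((cx, cy), d) in enumerate(zip(centers, diams))
    ]
    if return_clean:
        return mic, anns, clean
    return mic, anns


def scene_to_dataset(scenes, out_dir) -> dict:
    """Write scenes to disk as MRC + COCO JSON + coordinate tables.

    ``scenes`` is a list of ``(Micrograph, annotations)`` pairs.  Layout::

        out_dir/images/<name>.mrc
        out_dir/coords/<name>.tsv
        out_dir/annotations.json

    Returns a manifest dict of the paths written.
    """
    if not scenes:
        raise ValueError("scene list is empty")
    out = Path(out_dir)
    image_index: dict[str, tuple[int, int]] = {}
    all_anns: list[ParticleAnnotation] = []
    next_id = 1
    for mic, anns in scenes:
        write_mrc(mic, out / "images" / f"{mic.name}.mrc")
        write_coord_table(anns, out / "coords" / f"{mic.name}.tsv")
        image_index[mic.name] = mic.shape
        for a in anns:
            a = ParticleAnnotation(
                a.center_x, a.center_y, a.diameter, a.image_ref, next_id, a.category
            )
            next_id += 1
            all_anns.append(a)
    doc = export_coco(all_anns, image_index)
    save_coco(doc, out / "annotations.json")
    return {
        "images": sorted(str(p) for p in (out / "images").glob("*.mrc")),
        "coords": sorted(str(p) for p in (out / "coords").glob("*.tsv")),
        "annotations": str(out / "annotations.json"),
    }


def dataset_from_dir(path) -> list:
    """Re-read a dataset written by :func:`scene_to_dataset`."""
    root = Path(path)
    anns = import_coco(load_coco(root / "annotations.json"))
    by_image: dict[str, list[ParticleAnnotation]] = {}
    for a in anns:
        by_image.setdefault(a.image_ref, []).append(a)
    scenes = []
    for mrc_path in sorted((root / "images").glob("*.mrc")):
        mic = read_mrc(mrc_path)
        scenes.append((mic, by_image.get(mic.name, [])))
    return scenes
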