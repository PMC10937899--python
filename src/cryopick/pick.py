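"""Inference and post-processing: detections -> coordinate files.

Prediction slots whose most likely class is "no particle" are dropped;
the rest are rescaled to pixel coordinates of the un-padded micrograph
with the particle-class probability as confidence.  Per micrograph, only
candidates whose confidence lies in the 25th-100th percentile band are
retained (the percentile is computed over that micrograph's candidates
by default; a whole-dataset threshold is available by flag).  Retained
picks go to one box file per micrograph and a single merged STAR file.
No non-maximum suppression is applied anywhere: one-to-one set
prediction makes it unnecessary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from cryopick.io import (
    Micrograph,
    StarRecord,
    read_mrc,
    write_box,
    write_star,
)
from cryopick.losses import PARTICLE
from cryopick.model import ParticleTransformer, load_checkpoint
from cryopick.preprocess import DenoiseConfig, denoise

__all__ = ["PickedParticle", "decode_predictions", "percentile_filter", "pick"]


@dataclass
class PickedParticle:
    micrograph: str
    center_x: float  # pixels, x = column
    center_y: float  # pixels, y = row
    confidence: float  # particle-class probability
    width: float
    height: float

    def as_star_record(self) -> StarRecord:
        return StarRecord(self.micrograph, self.center_x, self.center_y,
                          self.confidence)


def decode_predictions(detections: dict, image_shape) -> list[PickedParticle]:
    """Turn one micrograph's N prediction slots into pixel-space picks."""
    h, w = image_shape
    probs = np.asarray(detections["class_probs"])
    boxes = np.asarray(detections["boxes"])
    name = detections.get("micrograph", "micrograph")
    keep = probs.argmax(axis=-1) == PARTICLE
    out = []
    for (cx, cy, bw, bh), p in zip(boxes[keep], probs[keep, PARTICLE]):
        out.append(
            PickedParticle(
                micrograph=name,
                center_x=float(cx * w),
                center_y=float(cy * h),
                confidence=float(p),
                width=float(bw * w),
                height=float(bh * h),
            )
        )
    return out


def percentile_filter(particles: list[PickedParticle],
                      percentile: float = 25.0) -> list[PickedParticle]:
    """Keep picks with confidence at or above the given percentile.

    The threshold is the linearly interpolated percentile of the
    candidate confidences; comparison is inclusive, so ties at the
    threshold are retained (with all-equal scores everything survives).
    An empty candidate list yields an empty result.
    """
    if not particles:
        return []
    scores = np.array([p.confidence for p in particles])
    threshold = np.percentile(scores, percentile, method="linear")
    return [p for p in particles if p.confidence >= threshold]


def write_overlay(micrograph: Micrograph, particles: list[PickedParticle],
                  path) -> None:
    """Cosmetic PNG with picked particles encircled on the micrograph."""
    from imageio.v3 import imwrite
    from skimage.draw import circle_perimeter

    from cryopick.preprocess import to_grayscale_uint

    canvas = np.stack([to_grayscale_uint(micrograph.pixels)] * 3, axis=-1)
    h, w = micrograph.shape
    for p in particles:
        radius = max(int(round((p.width + p.height) / 4)), 2)
        rr, cc = circle_perimeter(int(round(p.center_y)),
                                  int(round(p.center_x)), radius,
                                  shape=(h, w))
        canvas[rr, cc] = (0, 255, 0)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    imwrite(Path(path), canvas)


def pick(model: ParticleTransformer | str | Path, in_dir, out_dir,
         percentile: float = 25.0, per_dataset: bool = False,
         denoise_config: DenoiseConfig | None = None,
         use_denoised: bool = True, input_upscale: int = 1,
         overlay: bool = False) -> dict:
    """Run the picker over a directory of MRC micrographs.

    Writes ``<name>.box`` per micrograph plus a merged ``particles.star``
    under ``out_dir`` and returns a summary ``{micrograph: n_picks}``.
    ``model`` may be a loaded model or a checkpoint path.  With
    ``overlay`` a PNG with encircled picks is written per micrograph.
    """
    if not isinstance(model, ParticleTransformer):
        model, _ = load_checkpoint(model)
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    paths = sorted(in_dir.glob("*.mrc"))
    if not paths:
        raise FileNotFoundError(f"no .mrc micrographs under {in_dir}")
    if use_denoised:
        cfg = denoise_config or DenoiseConfig()
    else:
        from dataclasses import replace

        cfg = replace(DenoiseConfig.raw(), use_normalize=True)

    candidates: dict[str, list[PickedParticle]] = {}
    shapes: dict[str, tuple[int, int]] = {}
    originals: dict[str, Micrograph] = {}
    for path in paths:
        mic = read_mrc(path)
        shapes[mic.name] = mic.shape
        if overlay:
            originals[mic.name] = mic
        den = denoise(mic, cfg)
        if input_upscale != 1:
            from cryopick.train import upscale_pixels

            den = Micrograph(upscale_pixels(den.pixels, input_upscale),
                             den.name, den.pixel_size)
        det = model.detect(den)
        det["micrograph"] = mic.name
        # normalized boxes decode against the original (un-upsampled) extent
        candidates[mic.name] = decode_predictions(det, mic.shape)

    if per_dataset:
        pooled = [p for plist in candidates.values() for p in plist]
        if pooled:
            scores = np.array([p.confidence for p in pooled])
            thr = np.percentile(scores, percentile, method="linear")
            retained = {
                name: [p for p in plist if p.confidence >= thr]
                for name, plist in candidates.items()
            }
        else:
            retained = candidates
    else:
        retained = {
            name: percentile_filter(plist, percentile)
            for name, plist in candidates.items()
        }

    out_dir.mkdir(parents=True, exist_ok=True)
    merged: list[StarRecord] = []
    summary: dict[str, int] = {}
    for name in sorted(retained):
        records = [p.as_star_record() for p in retained[name]]
        write_box(records, out_dir / f"{name}.box")
        merged.extend(records)
        summary[name] = len(records)
        if overlay:
            write_overlay(originals[name], retained[name],
                          out_dir / f"{name}_picks.png")
    if merged:
        write_star(merged, out_dir / "particles.star")
    return summary
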