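"""End-to-end detection: segment a scene, classify every seed, annotate.

``detect_scene`` chains watershed segmentation, chip extraction and
classifier inference and returns one record per retained seed instance
(id, bbox, centroid, predicted class, class probability) plus an annotated
copy of the RGB planes with labelled bounding boxes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from PIL import Image, ImageDraw

from .cnn import CornSeedNet, predict
from .msimage import MultispectralImage
from .segmentation import SegmentationParams, extract_chips, watershed_segment

BOX_COLORS = {"good": (0, 170, 0), "bad": (220, 30, 30)}


@dataclass
class SeedDetection:
    instance_id: int
    bbox: tuple                    # (r0, c0, r1, c1), half-open
    centroid: tuple                # (row, col)
    predicted_class: str
    probability: float             # probability of the predicted class

    def to_dict(self):
        return {
            "id": self.instance_id,
            "bbox": [int(v) for v in self.bbox],
            "centroid": [round(float(v), 2) for v in self.centroid],
            "class": self.predicted_class,
            "prob": round(float(self.probability), 6),
        }


@dataclass
class DetectionResult:
    seeds: list = field(default_factory=list)
    scene: str = None
    instances: list = field(default_factory=list)   # the underlying SeedInstances

    def __len__(self):
        return len(self.seeds)

    def to_json(self) -> str:
        return json.dumps({"scene": self.scene,
                           "seeds": [s.to_dict() for s in self.seeds]}, indent=2)


def annotate(img: MultispectralImage, detections) -> np.ndarray:
    """RGB copy of the scene with class-coloured boxes and labels drawn."""
    pil = Image.fromarray(img.pixels[:, :, :3].copy())
    draw = ImageDraw.Draw(pil)
    for det in detections:
        r0, c0, r1, c1 = det.bbox
        color = BOX_COLORS.get(det.predicted_class, (0, 0, 255))
        draw.rectangle([c0, r0, c1 - 1, r1 - 1], outline=color, width=2)
        draw.text((c0 + 2, max(0, r0 - 12)),
                  f"{det.instance_id}:{det.predicted_class}", fill=color)
    return np.asarray(pil)


def detect_scene(img: MultispectralImage, params: SegmentationParams = None,
                 model: CornSeedNet = None, classifier=None):
    """Run the full pipeline on one scene.

    ``model`` is a trained CornSeedNet; alternatively ``classifier`` is any
    callable mapping a list of chips to a list of label strings (used for
    stubbed/oracle classifiers in tests).  Returns
    (DetectionResult, annotated RGB image).
    """
    params = params or SegmentationParams()
    if model is None and classifier is None:
        raise ValueError("either a trained model or a classifier callable is required")
    instances = watershed_segment(img, params)
    detections = []
    if instances:
        size = model.spec.input_size if model is not None else 224
        chips = extract_chips(img, instances, size=size)
        if model is not None:
            outputs = predict(model, chips)
            labels = [o.predicted_class for o in outputs]
            probs = [float(o.probs.max()) for o in outputs]
        else:
            labels = list(classifier(chips))
            probs = [1.0] * len(labels)
        for inst, lab, p in zip(instances, labels, probs):
            detections.append(SeedDetection(inst.instance_id, inst.bbox,
                                            inst.centroid, lab, p))
    result = DetectionResult(seeds=detections, scene=img.source_path, instances=instances)
    return result, annotate(img, detections)
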