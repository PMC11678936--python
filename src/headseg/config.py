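"""Run configuration: variant flags, thresholds, paths, and the training
hyper-parameter record.

The training hyper-parameters (lr 0.01, batch 16, momentum 0.937, weight decay
0.0005, 300 epochs) are carried verbatim for provenance — this package profiles
and runs inference; it does not train.  Confidence/NMS thresholds used for
evaluation are declared here as defaults, not inferred from any result table.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # variant flags
    c2f_dattention: bool = False
    adown: bool = False
    soep: bool = False
    n_classes: int = 1
    width_multiple: float = 0.25
    depth_multiple: float = 1 / 3
    # inference
    imgsz: int = 640
    conf_threshold: float = 0.25
    iou_threshold: float = 0.7
    mask_threshold: float = 0.5
    # reproducibility
    seed: int = 0
    # training hyper-parameter record (provenance only)
    train_record: dict = field(default_factory=lambda: {
        "lr": 0.01, "batch": 16, "momentum": 0.937,
        "weight_decay": 0.0005, "epochs": 300,
    })

    def __post_init__(self):
        if not (0 <= self.conf_threshold <= 1 and 0 <= self.iou_threshold <= 1):
            raise ValueError("thresholds must lie in [0, 1]")
        if self.imgsz % 32:
            raise ValueError("imgsz must be divisible by 32")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def load(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in data.items() if k in known})

    def variant(self):
        from .model_assembly import ModelVariant

        return ModelVariant(
            c2f_dattention=self.c2f_dattention, adown=self.adown,
            soep=self.soep, n_classes=self.n_classes,
            width_multiple=self.width_multiple,
            depth_multiple=self.depth_multiple)
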