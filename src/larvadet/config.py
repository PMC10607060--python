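"""Detector configuration: presets, YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path

import yaml


@dataclass
class DetectorConfig:
    # classes / features
    n_classes: int = 5
    backbone_widths: tuple[int, ...] = (32, 64, 128, 256)
    channels: int = 256                 # unified pyramid width
    head_width: int = 1024

    # module toggles (the ablation grid switches these independently)
    cfem_enabled: bool = True
    cfem_rate: int = 2                  # ASPP sampling rate
    cfem_image_pool: bool = True
    rffm_enabled: bool = True
    roi_size: int = 7
    tsm_enabled: bool = True
    cls_source: str = "P"               # pyramid feeding classification
    loc_source: str = "M"               # pyramid feeding localization
    cascade_stages: int = 1             # >1 is an untested configuration stub

    # anchors (one size per level P2..P6, three aspect ratios)
    anchor_sizes: tuple[int, ...] = (32, 64, 128, 256, 512)
    anchor_ratios: tuple[float, ...] = (0.5, 1.0, 2.0)

    # proposal stage
    rpn_pos_iou: float = 0.7
    rpn_neg_iou: float = 0.3
    rpn_batch: int = 256
    rpn_pos_fraction: float = 0.5
    rpn_pre_nms_topk: int = 1000        # per level
    rpn_nms_thr: float = 0.7
    max_proposals_train: int = 1000
    max_proposals_test: int = 300

    # RoI head
    head_fg_iou: float = 0.5
    roi_batch: int = 512
    roi_pos_fraction: float = 0.25
    bbox_reg_stds: tuple[float, ...] = (0.1, 0.1, 0.2, 0.2)
    add_gt_proposals: bool = True

    # test-time
    score_thr: float = 0.05
    test_nms_thr: float = 0.5
    max_detections: int = 100
    max_image_size: tuple[int, int] = (1333, 800)   # cap, applied only if exceeded

    # optimisation
    lr: float = 0.005
    momentum: float = 0.9
    weight_decay: float = 1e-4
    batch_size: int = 2
    epochs: int = 12
    lr_decay_epochs: tuple[int, ...] = (8, 11)
    lr_decay_factor: float = 0.1
    flip_prob: float = 0.5
    seed: int = 0

    def validate(self):
        if self.cls_source not in ("P", "M") or self.loc_source not in ("P", "M"):
            raise ValueError("cls_source/loc_source must be 'P' or 'M'")
        if self.cfem_rate < 1:
            raise ValueError("ASPP sampling rate must be >= 1")
        if len(self.anchor_sizes) != 5:
            raise ValueError("need one anchor size per level P2..P6")
        if self.cascade_stages != 1:
            raise NotImplementedError(
                "cascaded refinement heads are a configuration stub; only a "
                "single refined head is implemented")

    def with_toggles(self, cfem: bool, rffm: bool, tsm: bool) -> "DetectorConfig":
        return replace(self, cfem_enabled=cfem, rffm_enabled=rffm,
                       tsm_enabled=tsm)

    # -- YAML -------------------------------------------------------------
    def save(self, path):
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @staticmethod
    def load(path) -> "DetectorConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cfg = DetectorConfig(**{k: tuple(v) if isinstance(v, list) else v
                                for k, v in raw.items()})
        cfg.validate()
        return cfg


def default_config(**overrides) -> DetectorConfig:
    return replace(DetectorConfig(), **overrides)


def tiny_config(**overrides) -> DetectorConfig:
    """Desk-scale preset matched to the 128×128 synthetic tiny scenes."""
    base = DetectorConfig(
        n_classes=2,
        backbone_widths=(8, 16, 32, 64),
        channels=32,
        head_width=128,
        anchor_sizes=(16, 32, 64, 128, 256),
        rpn_batch=64,
        rpn_pre_nms_topk=300,
        max_proposals_train=200,
        max_proposals_test=100,
        roi_batch=96,
        lr=0.02,
        lr_decay_epochs=(),
    )
    return replace(base, **overrides)
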