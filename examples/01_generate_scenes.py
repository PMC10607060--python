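"""Generate a small annotated synthetic dataset and report its statistics.

Renders single-species scenes of striped larva-like capsules on cluttered
vegetation backgrounds, writes PNG images, Pascal-VOC XML annotations and a
JSON manifest, then summarises the instance scale mixture.
"""

import tempfile
from collections import Counter
from pathlib import Path

from larvadet import SceneSpec, make_dataset, read_voc_xml, scale_of_box

out_dir = Path(tempfile.mkdtemp(prefix="larvadet_scenes_"))
spec = SceneSpec(image_size=(800, 600), n_classes=5, similarity=0.8,
                 scale_mix=0.396)
manifest = make_dataset(spec, n_per_class=4, split_ratio=0.8, seed=0,
                        out_dir=out_dir)

print(f"dataset at {out_dir}")
print(f"classes: {manifest.class_names}")
print(f"train/test images: {len(manifest.paths('train'))} / "
      f"{len(manifest.paths('test'))}")

scales = Counter()
for entry in manifest.entries:
    _, boxes = read_voc_xml(entry.xml_path, manifest.class_names)
    for box in boxes.boxes:
        scales[scale_of_box(box)] += 1
total = sum(scales.values())
print(f"instances: {total}; scale mixture: " +
      ", ".join(f"{k} {100 * v / total:.0f}%" for k, v in scales.items()))
print("(the medium share converges to 39.6% as the dataset grows; "
      "each box is the analytic extent of the rendered larva)")
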