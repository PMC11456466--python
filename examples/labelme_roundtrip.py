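"""Read a Labelme polygon annotation and predict posture from it.

Builds a minimal Labelme-style JSON (one "head" polygon, one "root" polygon)
in a temporary directory, rasterizes it into masks and runs the pipeline —
the route a user takes when their segmenter or annotation tool emits
polygons rather than mask images.  The root polygon leans right, so the
printed theta is a two-digit tilt and the label is TILTED.
"""

import json
import tempfile
from pathlib import Path

from cabbagepose import predict_posture, scene_io

annotation = {
    "imageHeight": 200,
    "imageWidth": 200,
    "shapes": [
        {
            "label": "head",
            "points": [[60, 30], [140, 30], [150, 80], [100, 105], [50, 80]],
        },
        {
            "label": "root",
            "points": [[95, 104], [112, 102], [130, 168], [115, 172]],
        },
    ],
}

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "plant.json"
    path.write_text(json.dumps(annotation))
    scene = scene_io.read_labelme(path)
    result = predict_posture(scene, beta_deg=10.0)

print(f"head pixels : {int(scene.head.sum())}")
print(f"root pixels : {int(scene.root.sum())}")
print(f"theta       : {result.theta_deg:.2f} deg")
print(f"label       : {result.label.value}")
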