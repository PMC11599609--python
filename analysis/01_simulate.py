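"""Simulate the specimen batch: 13 carapaces, 3 cross-section classes.

Writes the labeled volumes (multi-page TIFF), the partition meshes with
per-face scute labels (PLY), the planted scute types, and the batch
manifest under results/simulated/.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from boxtess import io as btio                      # noqa: E402
from boxtess.synthetic import synthesize_carapace   # noqa: E402
from boxtess.pipeline import simulate_batch         # noqa: E402

OUT = Path(__file__).resolve().parents[1] / "results" / "simulated"
SEED = 42

if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    specs = simulate_batch(SEED, n_specimens=13,
                           geometry_classes=("elliptic", "triangular",
                                             "tetragonal"))
    rows, planted = [], []
    for i, spec in enumerate(specs):
        sid = f"synthetic_{i:02d}"
        partition, volume = synthesize_carapace(spec)
        btio.write_label_volume(OUT / f"{sid}.tif", volume)
        btio.write_ply(OUT / f"{sid}.ply", partition.mesh,
                       partition.face_label.astype(float), "scute_id")
        rows.append({"specimen": sid, **spec.__dict__})
        for scute, tp in sorted(partition.planted_type.items()):
            planted.append({"specimen": sid, "scute_id": scute,
                            "planted_type": tp})
        print(f"{sid}: {spec.geometry_class:10s} L={spec.length_mm:6.1f} mm"
              f"  {len(partition.scute_ids)} scutes")
    pd.DataFrame(rows).to_csv(OUT / "specs.csv", index=False)
    pd.DataFrame(planted).to_csv(OUT / "planted_types.csv", index=False)
    (OUT / "manifest.json").write_text(json.dumps(
        {"seed": SEED, "n_specimens": len(specs)}, indent=2))
    print(f"\nwrote batch to {OUT}")
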