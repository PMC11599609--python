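"""Scute-shape (neighbor-count) frequencies per specimen.

Proportions of k-neighbored scutes per specimen, excluding opening
scutes whose neighbor count is not comparable.  Writes
results/shapes/shape_frequencies.csv and prints the per-class ranges.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from boxtess.regions import shape_frequencies, SHAPE_CLASSES  # noqa: E402

BASE = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    records = pd.read_csv(BASE / "measured" / "scute_records.csv")
    out = BASE / "shapes"
    out.mkdir(parents=True, exist_ok=True)
    freq = shape_frequencies(records)
    freq.to_csv(out / "shape_frequencies.csv", index=False)
    print("per-specimen shape shares (percent):")
    for cls in SHAPE_CLASSES:
        col = freq[f"prop_{cls}"] * 100
        print(f"  {cls}-neighbored: {col.min():5.1f} - {col.max():5.1f} "
              f"(median {col.median():5.1f})")
    print(f"\nhexagons are the modal class in "
          f"{(freq[[f'prop_{c}' for c in SHAPE_CLASSES]].idxmax(axis=1) == 'prop_6').sum()}"
          f"/{len(freq)} specimens")
    print(f"wrote {out / 'shape_frequencies.csv'}")
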