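#!/usr/bin/env python
"""Label the feature table against histology annotations.

Maps annotation intervals from histology coordinates to the fresh core
under the uniform-deformation assumption, assigns each point the label of
its interval, and excludes the 25 points straddling every label
transition (~0.54 mm).
"""

import argparse
from pathlib import Path

import pandas as pd

from flimcore.io import read_annotations_csv, read_layouts_csv
from flimcore.labeling import build_labeled_dataset

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--dir", type=Path, default=Path("results/analysis"))
parser.add_argument("--n-exclude", type=int, default=25)
args = parser.parse_args()

features = pd.read_csv(args.dir / "features.csv")
tracks = read_annotations_csv(args.dir / "annotations.csv")
lengths = {l.core_id: l.fresh_length_mm for l in read_layouts_csv(args.dir / "layouts.csv")}

labeled = build_labeled_dataset(features, tracks, lengths, n_exclude=args.n_exclude)
labeled.to_csv(args.dir / "labeled.csv", index=False)

truth = pd.read_csv(args.dir / "truth.csv")
merged = labeled[labeled["pass_index"] == 0].merge(
    truth, on=["core_id", "position_mm"], suffixes=("", "_true")
)
acc = (merged["label"] == merged["label_true"]).mean()
print(f"labeled {len(labeled)} points; excluded {labeled['excluded'].mean():.1%} "
      f"near transitions; label accuracy vs ground truth {acc:.1%}")
print(labeled.loc[~labeled["excluded"], "label"].value_counts())
print(f"wrote {args.dir}/labeled.csv")
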