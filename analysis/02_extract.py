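#!/usr/bin/env python
"""Step 2 — extract the 42 fundus parameters from the rendered images.

Reads every image/landmark pair written by step 1 and produces the feature
table CSV, reporting how many eyes were measured and any exclusions.
"""

from pathlib import Path

from fundusage.colorimetry import extract_features
from fundusage.errors import FundusError
from fundusage.io import features_to_frame, read_image, read_landmarks, write_feature_csv

DATA = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    fixtures = DATA / "fixtures"
    rows, excluded = {}, []
    for lmk_path in sorted(fixtures.glob("*.json")):
        img_path = lmk_path.with_suffix(".png")
        try:
            rows[lmk_path.stem] = extract_features(
                read_image(img_path), read_landmarks(lmk_path)
            )
        except FundusError as exc:
            excluded.append((lmk_path.stem, str(exc)))
    out = DATA / "extracted_features.csv"
    write_feature_csv(out, features_to_frame(rows))
    print(f"extracted {len(rows)} eyes -> {out}; {len(excluded)} excluded")
    for eye, reason in excluded:
        print(f"  excluded {eye}: {reason}")


if __name__ == "__main__":
    main()
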