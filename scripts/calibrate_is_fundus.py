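"""Regenerate the seeded fundus-screen calibration set and report accuracy.

The set is 100 phantom fundus frames spanning realistic degradation (noise,
blur, pose jitter) and 100 non-fundus frames (25 of each kind), derived
deterministically from --seed.  The script sweeps candidate thresholds and
marks the shipped one; it is how the packaged IS_FUNDUS_THRESHOLD and
feature scales were frozen.

Usage:  python scripts/calibrate_is_fundus.py [--seed 0]
"""

import argparse

import numpy as np

from fundusavr.phantom import calibration_fixture_set
from fundusavr.screening import IS_FUNDUS_THRESHOLD, fundus_confidence


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    items = calibration_fixture_set(seed=args.seed)
    labels = np.array([lab for lab, _ in items])
    confs = np.array([fundus_confidence(img) for _, img in items])

    pos, neg = confs[labels], confs[~labels]
    print(f"fundus confidence:     min {pos.min():.3f}  median {np.median(pos):.3f}")
    print(f"non-fundus confidence: max {neg.max():.3f}  median {np.median(neg):.3f}")
    for thr in (0.3, 0.4, IS_FUNDUS_THRESHOLD, 0.6, 0.7):
        acc = np.mean((confs >= thr) == labels)
        mark = " <- shipped" if thr == IS_FUNDUS_THRESHOLD else ""
        print(f"threshold {thr:.2f}: accuracy {acc * 100:5.1f}%{mark}")


if __name__ == "__main__":
    main()
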