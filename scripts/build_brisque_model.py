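"""Build the shipped BRISQUE toy model.

Fits the feature centre and scales on a seeded ladder of clean synthetic
phantom slices (varied anatomy, no added noise) and writes the versioned
model JSON into the package data directory.  Rerunning reproduces the
file bit for bit.

Usage: python scripts/build_brisque_model.py
"""

from pathlib import Path

import numpy as np

from reconqc.synthetic_cohort import generate_phantom_slice
from reconqc.unpaired_metrics import train_toy_model

SEED = 20240101
N_IMAGES = 24
SIZE = 320


def main() -> None:
    rng = np.random.default_rng(SEED)
    images = []
    for _ in range(N_IMAGES):
        images.append(
            generate_phantom_slice(
                int(rng.integers(0, 2**31)),
                size=SIZE,
                body_axes=(rng.uniform(0.74, 0.90), rng.uniform(0.54, 0.70)),
                ring_radius=0.14 * rng.uniform(0.8, 1.2),
                layer_contrast=rng.uniform(0.8, 1.2),
                texture_amplitude=0.30 * rng.uniform(0.7, 1.3),
            )
        )
    model = train_toy_model(
        images,
        provenance=f"toy model: {N_IMAGES} clean synthetic phantoms, seed {SEED}",
    )
    out = Path(__file__).resolve().parent.parent / "src/reconqc/data/brisque_toy_model.json"
    model.save(out)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
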