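#!/usr/bin/env python
"""Generate the two synthetic pre-50S volume ensembles.

For each dataset (yjgA deletion; N-loop deletion) this writes a 500-row
occupancy matrix drawn from the per-class state templates at per-block
noise sd 0.05, the phantom block library, and a ground-truth sidecar, under
results/ensembles/<dataset>/.
"""

import json
from pathlib import Path

from ribohet.acceptance import TEMPLATE_SETS
from ribohet.blocks import save_block_library
from ribohet.occupancy import save_occupancy_matrix
from ribohet.synthetic import make_phantom, template_matrix

OUT = Path(__file__).resolve().parent.parent / "results" / "ensembles"
SEED = 1


def main() -> None:
    for dataset, factory in TEMPLATE_SETS.items():
        out = OUT / dataset
        out.mkdir(parents=True, exist_ok=True)
        templates = factory()
        matrix = template_matrix(templates, n_volumes=500, noise_sd=0.05, seed=SEED)
        save_occupancy_matrix(matrix, out / "occupancy_matrix.tsv")
        _, library = make_phantom(seed=SEED)
        save_block_library(library, out / "blocks.yaml")
        truth = {
            "dataset": dataset,
            "seed": SEED,
            "noise_sd": 0.05,
            "n_volumes": 500,
            "classes": [t.class_id for t in templates],
            "states": [t.name for t in templates],
            "weights": [t.weight for t in templates],
            "template_index": matrix.attrs["template_index"].tolist(),
        }
        (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
        print(f"{dataset}: 500 volumes x {matrix.shape[1] - 2} blocks, "
              f"{len(templates)} planted classes -> {out}")


if __name__ == "__main__":
    main()
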