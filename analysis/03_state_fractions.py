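#!/usr/bin/env python
"""State-fraction recovery at full particle scale and dataset comparison.

Simulates 200 000 particles per dataset with the reported per-state
weights, runs the complete pipeline (latent k-means into 500 volumes ->
ward classification -> taxonomy -> particle-weighted fractions), writes the
state summaries and their delta table. The headline check: the state-2
marginal is ~56% without the assembly factor and drops to ~27% when the
N-loop-deleted variant is reintroduced, while state 3 rises from ~20% to
~52%.
"""

from pathlib import Path

from ribohet.acceptance import recover_state_fractions
from ribohet.taxonomy import compare_state_distributions

OUT = Path(__file__).resolve().parent.parent / "results" / "states"
SEED = 1
N_PARTICLES = 200_000


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    summaries = {}
    for dataset in ("delta_yjga", "delta_nloop"):
        summary = recover_state_fractions(dataset, n_particles=N_PARTICLES, seed=SEED)
        summaries[dataset] = summary
        summary.to_frame().to_csv(OUT / f"{dataset}_state_summary.tsv", sep="\t")
        marginal = summary.ptc_marginal()
        print(f"{dataset}: PTC-stage marginals "
              + ", ".join(f"state {s}: {100 * f:.1f}%" for s, f in marginal.items()))
    delta = compare_state_distributions(
        summaries["delta_yjga"], summaries["delta_nloop"]
    )
    delta.to_csv(OUT / "state_delta.tsv", sep="\t")
    print("wrote state summaries and delta table to", OUT)


if __name__ == "__main__":
    main()
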