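#!/usr/bin/env python
"""Generate the labeled synthetic benchmark used by the downstream steps.

Emits 5 ureido-forming and 20 canonical amide-forming condensation-domain
proteins (~450-residue domains embedded between 150-residue random flanks
carrying decoy near-motifs) plus 5 motif-free decoy-only negatives, at a
column-wise conservation level of 0.7, under results/benchmark/.
"""

from pathlib import Path

from ureidoscan.simulate import SynthConfig, make_benchmark

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    config = SynthConfig(
        n_urea=5, n_canonical=20, n_decoy_only=5, identity=0.7, seed=17
    )
    paths = make_benchmark(config, RESULTS / "benchmark")
    print(f"wrote {paths['fasta']}")
    print(f"wrote {paths['truth']}")
    print(f"wrote {paths['labels']}")
    print(
        f"benchmark: {config.n_urea} urea + {config.n_canonical} amide + "
        f"{config.n_decoy_only} decoy-only proteins, identity {config.identity}, "
        f"seed {config.seed}"
    )


if __name__ == "__main__":
    main()
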