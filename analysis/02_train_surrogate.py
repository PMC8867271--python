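"""Train the POD + GP surrogate on the stored training dataset.

For each quantity of interest, 100 randomly chosen responses form the
snapshot matrix; the SVD basis is truncated at 99.9% relative energy and one
ARD-RBF Gaussian process is fitted per retained projection coefficient.
Writes the model archive under results/model/."""

import argparse
from pathlib import Path

from isruq import surrogate as surr
from isruq.io import derive_seeds, read_dataset

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=0)
ap.add_argument("--dataset", type=Path, default=Path("results/dataset"))
ap.add_argument("--out", type=Path, default=Path("results/model"))
ap.add_argument("--snapshots", type=int, default=100)
ap.add_argument("--energy", type=float, default=0.999)
args = ap.parse_args()

seeds = derive_seeds(args.seed)
ds = read_dataset(args.dataset)
model = surr.train(ds, n_snapshots=args.snapshots,
                   energy_threshold=args.energy, seed=seeds["train"])
model.save(args.out)

for q, qs in model.per_qoi.items():
    print(f"{q}: retained rank k={qs.basis.k} "
          f"(relative energy {qs.basis.relative_energy:.6f})")
print(f"model archive -> {args.out}")
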