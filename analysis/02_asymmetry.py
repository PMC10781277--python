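"""Score movement asymmetry on a synthetic dataset.

Computes the per-segment log energy-ratio asymmetry score and the
absolute-asymmetry (AAS) summary by movement type; unimanual movements
should score far above bimanual-asymmetric ones, which in turn exceed
bimanual-symmetric ones.  Writes results/aas_by_movement_type.csv and
results/asymmetry_per_segment.csv.
"""

import argparse
from pathlib import Path

from imuhar.asymmetry import aas_by_movement_type, asymmetry_table
from imuhar.synthetic import SyntheticSpec, generate_dataset


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=17)
    parser.add_argument("--out-dir", default="results")
    args = parser.parse_args()

    spec = SyntheticSpec(task="ADL", n_nd=8, n_stroke=4, n_classes=18,
                         length_mean=300.0, length_sd=60.0, length_floor=120,
                         seed=args.seed)
    synth = generate_dataset(spec)
    table = asymmetry_table(synth.dataset)
    summary = aas_by_movement_type(synth.dataset)

    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "asymmetry_per_segment.csv", index=False,
                 float_format="%.4f")
    summary.to_csv(out / "aas_by_movement_type.csv", index=False,
                   float_format="%.4f")

    print(f"{len(table)} segments scored; AAS by movement type:")
    print(summary.round(3).to_string(index=False))
    ordered = summary.set_index("movement_type")["mean_aas"]
    assert ordered["UNI"] > ordered["BIA"] > ordered["BIS"]
    print("ordering UNI > BIA > BIS holds")


if __name__ == "__main__":
    main()
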