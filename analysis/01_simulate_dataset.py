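#!/usr/bin/env python
"""Generate the synthetic study dataset.

Writes, under results/simulated/:

* ROI fluorescence traces (flash-off-gray protocol) for three genotypes ×
  seven compartments, with the default effect map (experimental responses
  halved in cell body/Lo1/Lo4, unchanged in M1/M8/M10, tripled in M5),
* the nominal stimulus log and the generator ground truth,
* 3D spot clouds for six specimens with a planted 90% double-labeled
  fraction (the inversion-efficiency input),
* Ct tables for a heterozygous null (true fraction 0.5) and
* progeny counts for the balancer complementation cross.
"""

import argparse
import json
from pathlib import Path

from flpstop_pipeline import SimConfig, generate_roi_traces
from flpstop_pipeline import io as fio
from flpstop_pipeline.stats import CrossSpec
from flpstop_pipeline.synthetic import (
    generate_cell_cloud,
    generate_cross_counts,
    generate_ct_table,
)

GENOTYPES = ("experimental", "no_flp_control", "het_control")
COMPARTMENTS = ("cell_body", "M1", "M5", "M8", "M10", "Lo1", "Lo4")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/simulated"))
    ap.add_argument("--n-rois", type=int, default=4, help="ROIs per condition")
    ap.add_argument("--n-trials", type=int, default=8, help="light flashes per ROI")
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    cfg = SimConfig(
        seed=args.seed, n_rois=args.n_rois, n_trials=args.n_trials,
        conditions=[(g, c) for g in GENOTYPES for c in COMPARTMENTS],
    )
    traces, log, truth = generate_roi_traces(cfg)
    fio.write_traces_csv(traces, out / "traces.csv")
    fio.write_stimulus_log_json(log, out / "stimulus_log.json")
    fio.write_json(truth.to_json_dict(), out / "traces_ground_truth.json")
    print(f"traces: {len(traces)} ROIs ({len(GENOTYPES)} genotypes × "
          f"{len(COMPARTMENTS)} compartments × {args.n_rois}), "
          f"{args.n_trials} light flashes each")

    spot_sets = []
    coloc_truth = {}
    for s in range(6):
        a, b, t = generate_cell_cloud(
            n_a=70, coloc_fraction=0.9, jitter_um=1.0, decoys=8,
            volume_um3=60.0**3, seed=args.seed * 100 + s)
        a.specimen_id = b.specimen_id = f"specimen{s + 1}"
        spot_sets += [a, b]
        coloc_truth[a.specimen_id] = t.to_json_dict()
    fio.write_spots_csv(spot_sets, out / "spots.csv")
    fio.write_json(coloc_truth, out / "spots_ground_truth.json")
    print("spot clouds: 6 specimens, 70 GFP spots each, planted fraction 0.90")

    ct, _ = generate_ct_table(true_fraction=0.5, replicate_sd=0.15,
                              n_bio=4, n_tech=4, seed=args.seed)
    fio.write_ct_csv(ct, out / "ct.csv")
    print("Ct table: true transcript fraction 0.50, 4 biological × 4 technical")

    cross = CrossSpec(
        parent1=("FlpStop_ND", "Balancer"), parent2=("Null", "Balancer"),
        scored_class=("FlpStop_ND", "Null"),
    )
    counts, cross_truth = generate_cross_counts(cross, n=400, seed=args.seed)
    fio.write_counts_csv(counts, out / "cross_counts.csv")
    fio.write_json(cross_truth.to_json_dict(), out / "cross_ground_truth.json")
    print("cross counts: 400 progeny, expected scored-class fraction "
          f"{cross_truth.class_probabilities['FlpStop_ND/Null']:.3f}")
    print(f"wrote dataset to {out}")


if __name__ == "__main__":
    main()
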