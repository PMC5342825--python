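#!/usr/bin/env python
"""Genetics and expression statistics on the simulated tables.

Three analyses:

1. Complementation lethality — observed FlpStop/Null survival in the
   simulated balancer cross vs the Mendelian expectation of 1/3 (33%),
   one-proportion z-test.
2. Paralysis counts — a two-tailed Fisher's exact test comparing a
   temperature-sensitive genotype to its control.
3. qRT-PCR — ΔΔCt relative transcript level from the simulated Ct table
   (true fraction 0.50, the expected level for a null allele over a
   functional copy), with a Student's t-test on the per-replicate ΔCt.
"""

import argparse
import sys
from pathlib import Path

from flpstop_pipeline import (
    delta_delta_ct,
    expected_survival,
    fisher_exact_2x2,
    one_proportion_ztest,
)
from flpstop_pipeline import io as fio
from flpstop_pipeline.stats import CrossSpec


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--simulated", type=Path, default=Path("results/simulated"))
    ap.add_argument("--out", type=Path, default=Path("results/genetics"))
    args = ap.parse_args()
    if not (args.simulated / "cross_counts.csv").exists():
        sys.exit(f"no tables in {args.simulated}; run 01_simulate_dataset.py first")
    args.out.mkdir(parents=True, exist_ok=True)
    results = {}

    # 1. survival vs the Mendelian expectation
    cross = CrossSpec(
        parent1=("FlpStop_ND", "Balancer"), parent2=("Null", "Balancer"),
        scored_class=("FlpStop_ND", "Null"),
    )
    p0 = expected_survival(cross)
    counts = fio.read_counts_csv(args.simulated / "cross_counts.csv")
    counts = counts.set_index("genotype_class")["count"]
    k, n = int(counts["FlpStop_ND/Null"]), int(counts.sum())
    z = one_proportion_ztest(k, n, p0)
    results["survival"] = {
        "expected": p0, "observed": k / n, "k": k, "n": n,
        "z": z.statistic, "p": z.p_value, "tier": z.tier,
    }
    print(f"survival: expected {p0:.3f} (33%), observed {k}/{n} = {k/n:.3f}, "
          f"z = {z.statistic:+.2f}, p = {z.p_value:.3f} ({z.tier})")

    # 2. paralysis: a fully penetrant TS genotype vs an unaffected control
    paralyzed = [[14, 1], [0, 15]]  # [TS paralyzed, not], [control paralyzed, not]
    f = fisher_exact_2x2(paralyzed)
    results["paralysis"] = {"table": paralyzed, "p": f.p_value, "tier": f.tier}
    print(f"paralysis Fisher's exact: 14/15 vs 0/15 paralyzed, "
          f"p = {f.p_value:.2e} ({f.tier})")

    # 3. transcript knock-down
    ct = fio.read_ct_csv(args.simulated / "ct.csv")
    dd = delta_delta_ct(ct)
    results["transcript"] = {
        "percent": dd["percent_transcript"],
        "t": dd["test"].statistic, "p": dd["test"].p_value,
        "tier": dd["test"].tier,
        "per_replicate_percent": {
            f"{genotype}/bio{bio}": v
            for (genotype, bio), v in dd["per_replicate_percent"].items()
        },
    }
    print(f"transcript level (D vs ND): {dd['percent_transcript']:.1f}% "
          f"(true 50%), t-test on ΔCt p = {dd['test'].p_value:.2e} "
          f"({dd['test'].tier})")

    fio.write_json(results, args.out / "genetics_stats.json")
    print(f"wrote {args.out / 'genetics_stats.json'}")


if __name__ == "__main__":
    main()
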