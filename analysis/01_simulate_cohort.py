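#!/usr/bin/env python
"""Simulate the study cohort: 12 mild-bias and 12 heavy-bias samples.

Each sample is a genome-wide 1 Mb window count profile of the LOUCY
truth karyotype at depth 0.8x with 75 bp reads, on the hg19-like female
genome (chrY excluded).  The mild group carries only weak lognormal
scatter (a well-behaved amplification); the heavy group adds
Pareto-tailed regional hotspots and dropout regions (a strongly biased
amplification).  Profiles and configs are written under
results/cohort/ for the downstream drivers.
"""

from pathlib import Path

from shallowcna import BiasModel, SimulationConfig, hg19_genome, loucy_truth_set, simulate_window_counts

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"

MILD = BiasModel("lognormal", sigma=0.1)
HEAVY = BiasModel(
    "hotspot", sigma=0.3, hotspot_rate=40, hotspot_gain=1.0,
    dropout_prob=0.2, dropout_factor=0.05,
)
N_PER_GROUP = 12
BASE_SEED = 20_000


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome = hg19_genome(include_chrY=False)
    truth = tuple(loucy_truth_set(genome))
    for group, bias, seed0 in (("mild", MILD, BASE_SEED), ("heavy", HEAVY, BASE_SEED + 1000)):
        for rep in range(N_PER_GROUP):
            cfg = SimulationConfig(genome=genome, truth=truth, seed=seed0 + rep, bias=bias)
            prof = simulate_window_counts(cfg)
            stem = OUT / f"{group}_{rep:02d}"
            prof.to_tsv(stem.with_suffix(".counts.tsv"))
            cfg.to_yaml(stem.with_suffix(".config.yaml"))
            mean = prof.df["raw_count"].mean()
            print(f"{group} rep {rep:02d}: {len(prof.df)} windows, mean count {mean:,.0f}")
    print(f"\nwrote {2 * N_PER_GROUP} samples to {OUT}")


if __name__ == "__main__":
    main()
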