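"""Simulate a bisulfite library and check metrics against closed forms.

With independent per-CpG calls at level p on k-CpG reads, the expected
weighted concurrence is (1-p)(1 - (1-p)^(k-1)): an unmethylated CpG is a
concurrence observation unless its whole read happens to be unmethylated.
Raising the within-read persistence rho makes reads concordant and drains
concurrence without moving mean methylation.
"""

from methconc import (
    GenomicInterval,
    SimulationConfig,
    concurrence_ratio,
    expected_concurrence_iid,
    mean_methylation,
    simulate_epireads,
)

genome = GenomicInterval("chrSim", 0, 10**9)

for rho in (0.0, 0.5, 0.9):
    config = SimulationConfig(n_cpgs=2000, coverage=50, cpgs_per_read=4,
                              p_meth=0.5, rho=rho, seed=7)
    records, truth = simulate_epireads(config)
    measured = concurrence_ratio(records, genome)
    mean = mean_methylation(records, genome)
    print(f"rho={rho:.1f}: concurrence measured {measured:.4f} "
          f"(expected {truth.expected_concurrence:.4f}), "
          f"mean methylation {mean:.4f} (expected {truth.expected_mean_meth})")

print(f"\nclosed form at p=0.5, k=4: {expected_concurrence_iid(0.5, 4)} "
      "(the rho=0 expectation above)")
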