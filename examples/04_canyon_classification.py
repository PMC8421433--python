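"""Call undermethylated regions and stratify canyons by concurrence.

Two large undermethylated valleys sit in a heavily methylated background.
The first is fully unmethylated: stable demethylation, no concurrence (an
"active" canyon). The second keeps a low but non-zero methylation level on
otherwise unmethylated reads, the read-level footprint of methylation and
demethylation acting on the same molecules (a Polycomb-like canyon). Both
are invisible to mean methylation — the concurrence ratio separates them
against a threshold fitted from random background regions.
"""

import numpy as np

from methconc import (
    SimulationConfig,
    call_canyons,
    call_umrs,
    classify_canyons,
    fit_background,
    meth_track_from_records,
    sample_background,
    simulate_epireads,
)
from methconc.canyons import CanyonCall
from methconc.concurrence import batch_region_concurrence, cpg_label_counts

config = SimulationConfig(n_cpgs=3000, cpg_spacing=100, coverage=50,
                          p_meth=0.95, seed=21)
# per-CpG methylation levels: methylated background with two valleys
positions = np.arange(3000) * 100 + 1100
p_per_cpg = np.full(3000, 0.95)
p_per_cpg[(positions >= 60_000) & (positions < 68_000)] = 0.0   # active
p_per_cpg[(positions >= 150_000) & (positions < 155_000)] = 0.04  # Polycomb-like
records, _ = simulate_epireads(config, p_per_cpg=p_per_cpg)

track = meth_track_from_records(records)["chrSim"]
umrs = call_umrs(track, min_run=4, max_meth=0.10)
canyons = call_canyons(umrs, min_length_bp=3500)
print(f"called {len(umrs)} UMRs, {len(canyons)} canyons:")

counts = cpg_label_counts(records)
conc = batch_region_concurrence(counts, [c.interval for c in canyons])
canyons = [CanyonCall(c.umr, concurrence=v) for c, v in zip(canyons, conc)]

# genome background: concurrence of random 1 kb regions
background = sample_background({"chrSim": 300_000}, n=120, lengths=1000,
                               seed=config.seed)
bg_values = [v for v in batch_region_concurrence(counts, background)
             if v is not None]
fit = fit_background(bg_values)
print(f"background fit: best family '{fit.best_family}', "
      f"90th-percentile threshold {fit.threshold:.4f}")

for c in classify_canyons(canyons, fit):
    r = c.interval
    print(f"  {r.chrom}:{r.start}-{r.end}  mean_meth={c.umr.mean_meth:.3f}"
          f"  concurrence={c.concurrence:.4f}  -> {c.klass}")
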