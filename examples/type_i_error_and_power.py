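"""Operating characteristics: type-I error and power by simulation.

Estimates the rejection rate of the test over replicated synthetic studies.
With d = 0 the phenotype is independent of the genotype, so the rate is the
type-I error and should sit near the nominal level; with d > 0 it is power.
A reduced replication count keeps this demo quick; scale `replications`
and `A` up (1000 each) for production-grade estimates.
"""

from ovrv import SimulationConfig, estimate_rejection_rate

for d in (0.0, 0.4, 0.8):
    cfg = SimulationConfig(
        n=500, m=20, d=d, alpha=0.05, replications=200, A=500, seed=11
    )
    rate, se = estimate_rejection_rate(cfg)
    label = "type-I error" if d == 0 else "power"
    print(f"d = {d:.1f}: {label} at alpha = 0.05 -> {rate:.3f} (MC se {se:.3f})")
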