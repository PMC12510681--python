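"""Inject known interaction effects into synthetic mixtures and recover them.

Generates two-species pot communities where observed yields are the
competitive expectations distorted by chosen multipliers delta (+20% on
species 1, -30% on species 2), then checks that the pipeline returns the
injected community deviation exactly.
"""

import comppart as cp

spec = cp.SyntheticSpec(seed=42, deltas=(0.2, -0.3), n_communities=4)
for report in cp.recover_injected_effects(spec):
    print(
        f"{report.mixture_id}: injected {report.injected_deviation:+.4f}, "
        f"recovered {report.recovered_deviation:+.4f} "
        f"(|error| = {report.abs_error:.1e}); "
        f"competitive component {report.competitive_effect:+.4f}"
    )
print(
    "\nRecovered positive+negative deviation equals sum(Y_CE_i * delta_i) to"
    "\nfloating point: the partition separates injected interaction effects"
    "\nfrom the competitive shift it derives from the monocultures."
)
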