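"""Species-level interaction classes in the simulated aspen-spruce stands.

For each stand, compares every species' observed yield with its competitive
expectation (positive / neutral / negative) and with its partial-density
monoculture (facilitative). In this chronosequence, facilitation appears
only on spruce in the mature, nearly pure spruce stand.
"""

import comppart as cp

dataset = cp.load_fixture("trees")
for com in dataset:
    part = cp.partition_community(com)
    classes = ", ".join(
        f"{s.species_id}: {s.interaction_class} "
        f"(Y_O={s.y_obs:.1f}, Y_CE={s.y_ce:.1f})"
        for s in part.species
    )
    print(f"{com.mixture_id:28s} {classes}")
print(
    "\n'facilitative' = the species outyields its own thinned monoculture;"
    "\nsign classes compare observed yield with the competitive expectation"
    "\ninside a 5% neutrality band."
)
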