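"""Generate a study-sized synthetic wing dataset and recover its modules.

Builds a 24-specimen dataset (21 reference landmarks on the wing veins,
19 measurement points on the pattern) with four planted variational
modules, runs superimposition, transfer, Rv correlation, thresholding at
0.2 and repeated spin-glass annealing, then prints the most frequent
modular architecture with each module's reproducibility.
"""

from mcnet import AnnealConfig, analyze
from mcnet.synthetic import generate, paper_shaped_spec

syn = generate(paper_shaped_spec("oexcavata_like", seed=0))
result = analyze(
    syn.dataset, tau=0.2, config=AnnealConfig(trials=500, master_seed=1)
)

top = result.table.top
print(f"planted modules:   {[list(m) for m in syn.planted_partition.modules]}")
print(f"recovered modules: {[list(m) for m in top.partition.modules]}")
print(f"top-solution frequency: {100 * top.frequency:.1f}% of {result.table.trials} trials")
for module in top.partition.modules:
    rep = result.table.module_reproducibility(module)
    print(f"  module {{{', '.join(module)}}}: reproducibility {100 * rep:.1f}%")
print(
    "A reproducibility near 100% means the annealer lands on that exact "
    "node set as one module in nearly every trial: the energy landscape "
    "has a single dominant basin, i.e. the modular architecture is unambiguous."
)
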