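"""Robustness of the detected architecture: threshold sweep and leave-one-out.

A detected modular architecture is only credible if it does not hinge on
the particular threshold chosen or on any single specimen.  The sweep
re-extracts modules at several threshold levels; the leave-one-out
analysis re-runs the entire pipeline on every n-1 subset.
"""

from mcnet import AnnealConfig, gpa, leave_one_out, rv_matrix, threshold_sweep, transfer
from mcnet.synthetic import SyntheticSpec, generate

spec = SyntheticSpec(
    n_specimens=12,
    k_reference=8,
    modules=(("MP1", "MP2", "MP3"), ("MP4", "MP5", "MP6"), ("MP7", "MP8")),
    module_effect_sd=0.15,
    noise_sd=0.02,
    seed=3,
)
syn = generate(spec)
config = AnnealConfig(trials=100, master_seed=5)

aligned = transfer(gpa(syn.dataset), syn.dataset)
sweep = threshold_sweep(rv_matrix(aligned), [None, 0.2, 0.4], config)
print("threshold sweep (none / 0.2 / 0.4):")
for tau, table in zip(sweep.taus, sweep.tables):
    label = "none" if tau is None else f"{tau:.1f}"
    print(f"  tau {label:>4}: top solution {[list(m) for m in table.top.partition.modules]}")
print(f"  identical top architecture at every level: {sweep.all_agree}")

loo = leave_one_out(syn.dataset, 0.2, config)
print(
    f"leave-one-out: {sum(loo.agreement)}/{len(loo.agreement)} subsets "
    f"reproduce the full-sample architecture "
    f"(agreement {loo.agreement_fraction:.2f}, stable={loo.stable})"
)
print(
    "Threshold agreement shows the architecture is not an artifact of the "
    "cutoff; any leave-one-out flips show that at this sample size single "
    "specimens can still tip the correlation structure - exactly what the "
    "diagnostic is there to reveal."
)
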