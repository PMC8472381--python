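"""Absolute 16S quantification from spiked-standard qPCR readouts.

The ratio of the exponentially amplified spike and 16S signals cancels the
DNA extraction yield, so 3e5 spiked copies anchor an absolute census. The
end-point census is additionally corrected for culture volume removed
during the experiment for plaque titrations.
"""

from phagesip import (
    QpcrMeasurement,
    SpikeStandard,
    quantify_sample,
    total_growth_fold,
)

spike = SpikeStandard(copies_spiked=300_000)

initial = quantify_sample(
    QpcrMeasurement("internal_standard", efficiency=0.798, ct=23.462),
    QpcrMeasurement("target_16s", efficiency=0.828, ct=13.215),
    spike,
)
final = quantify_sample(
    QpcrMeasurement("internal_standard", efficiency=0.845, ct=24.461),
    QpcrMeasurement("target_16s", efficiency=0.801, ct=14.133),
    spike,
    volume_removed_ul=240,
    bottle_volume_ul=5200,
)

print(f"initial: {initial.fold_over_spike:.0f}-fold over the spike "
      f"-> {initial.total_16s_copies:.3g} 16S copies")
print(f"final:   {final.fold_over_spike:.0f}-fold over the spike "
      f"-> {final.total_16s_copies:.3g} 16S copies "
      "(corrected for sampled volume)")
print(f"community growth: {total_growth_fold(initial.total_16s_copies, final.total_16s_copies):.2f}-fold "
      "increase in total 16S copies over the incubation")
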