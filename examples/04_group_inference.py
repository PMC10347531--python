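"""Permutation/FDR group comparison on a cohort with one injected difference.

Six CEN -> SN couplings in the 0.04-0.08 Hz band are stronger in patients;
the block-level permutation test should flag exactly that network block.
"""

import numpy as np

from freqec import CohortSpec, CouplingEdge, conditional_gc, generate_cohort, run_group_analysis
from freqec._filters import zero_phase_bandpass
from freqec.decompose import FOIBand

edges = tuple(
    CouplingEdge(source=13 + i, target=9 + (i % 4), band=1, lag=1,
                 strength_controls=0.1, strength_patients=0.6)
    for i in range(6)
)
spec = CohortSpec(coupling_edges=edges, seed=42)  # 49 patients + 54 controls
metadata, tcs, _ = generate_cohort(spec)

bands = [FOIBand(0.12, 0.18, name="FOI-1"), FOIBand(0.04, 0.08, name="FOI-2")]
ec_by_band = {}
for band in bands:
    filt = zero_phase_bandpass(tcs.data, band.low, band.high, 0.5, order=4)
    ec_by_band[band.name] = np.stack(
        [np.nan_to_num(conditional_gc(filt[s], p=1).values) for s in range(len(metadata))]
    )

result = run_group_analysis(ec_by_band, metadata, spec.network_labels,
                            q=0.05, n_perm=2000, seed=9)
sig = result.blocks[result.blocks["significant"]]
print(sig[["band", "source", "target", "stat", "p_raw", "p_fdr"]].to_string(index=False))
# 'stat' is the patient-minus-control difference of the block-mean causality;
# the injected CEN -> SN block in FOI-2 carries the largest positive difference.
# Its reverse block often co-flags with a smaller effect: zero-phase band
# limiting smears a lagged interaction symmetrically in time.
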