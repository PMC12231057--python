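"""EEG-fMRI fusion: which model explains the cross-modal shared variance?

Combines the group-averaged EEG RDM series (alpha and beta) from step 04
with the group network RDMs from step 03 and partitions their shared
variance between the RC and CE models via commonality analysis with
permutation inference.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from relfusion import io as rio
from relfusion.containers import RdmSeries
from relfusion.fusion import FusionInputs, fusion_pipeline
from relfusion.synth import NETWORKS

OUT = Path("results")
SEED = 1
N_PERM = 1000

if __name__ == "__main__":
    rc = rio.read_rdm(OUT / "model_rc")
    ce = rio.read_rdm(OUT / "model_ce")
    nets = {n: rio.read_rdm(OUT / f"network_rdm_{n}") for n in NETWORKS}
    rows = []
    for band in ("alpha", "beta"):
        stack = np.load(OUT / f"group_eeg_rdms_{band}.npy")
        centers = -0.4 + (np.arange(stack.shape[0]) + 0.5) * 0.1
        series = RdmSeries(stack, rc.puzzle_ids, centers, 0.1, band=band)
        res = fusion_pipeline(FusionInputs(series, nets, rc, ce),
                              n_perm=N_PERM, seed=SEED, fdr_method="bh")
        for net in ("frontoparietal", "dorsal-attention",
                    "cingulo-opercular", "default"):
            tc = res[net]
            k = int(np.argmax(tc.total_r2))
            n_sig = int(np.sum(tc.sig_rc))
            print(f"  {band:<6} {net:<18} peak R2 = {tc.total_r2[k]:.3f} "
                  f"at {tc.bin_centers[k]:.2f} s; C(RC) = {tc.c_rc[k]:+.3f}, "
                  f"C(CE) = {tc.c_ce[k]:+.3f}; {n_sig} significant RC bin(s)")
        rows += [tc.to_frame() for tc in res.values()]
    pd.concat(rows, ignore_index=True).to_csv(OUT / "fusion.tsv", sep="\t",
                                              index=False)
    print(f"wrote fusion timecourses to {OUT}/fusion.tsv")
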