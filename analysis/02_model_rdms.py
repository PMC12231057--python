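"""Build the two candidate model RDMs and measure their similarity.

The theoretical relational-complexity (RC) model grades puzzle dissimilarity
by the ordinal complexity gap; the data-driven cognitive-effort (CE) model is
the Euclidean distance between puzzles' standardized (error rate, RT)
profiles pooled over both arms.  Prints their rank correlation (the study
reported r_s = 0.81 on real data).
"""

from pathlib import Path

from relfusion import io as rio
from relfusion.models import build_ce_model, build_rc_model, \
    model_model_correlation

OUT = Path("results")

if __name__ == "__main__":
    beh_f = rio.read_behaviour(OUT / "behaviour_fmri.tsv")
    beh_e = rio.read_behaviour(OUT / "behaviour_eeg.tsv")
    from relfusion.synth import GeneratorConfig
    puzzles = GeneratorConfig().puzzle_set("fmri")
    rc = build_rc_model(puzzles)
    ce = build_ce_model(beh_f, beh_e)
    for name, model in (("model_rc", rc), ("model_ce", ce)):
        rio.write_rdm(OUT / name, model)
        rio.rdm_to_long_tsv(OUT / f"{name}.tsv", model)
    rs = model_model_correlation(rc, ce)
    print(f"RC-CE model similarity: r_s = {rs:.3f}")
    print(f"wrote model RDMs to {OUT}/")
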