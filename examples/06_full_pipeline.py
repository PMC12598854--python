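"""The whole workflow in one call: trajectory -> DRID -> states -> network
-> disconnectivity graph -> FPT distributions.

Stages are cached by content hash in manifest.json: re-running with an
unchanged config skips everything.
"""

import tempfile
from pathlib import Path

import dridscape as ds
from dridscape.pipeline import RunConfig, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    pl = ds.make_landscape(4, "chain", seed=5)
    st = ds.sample_state_trajectory(pl, 20_000, frame_interval=20.0, seed=6)
    templates = ds.make_templates(4, seed=7)
    top, xtc = ds.emit_toy_trajectory(st, templates, seed=8,
                                      out_prefix=tmp / "toy")

    cfg = RunConfig(topology=str(top), trajectory=str(xtc),
                    centroids="resid 1 5 8 and name CA", reference="name CA",
                    cutoff=templates.suggested_cutoff,
                    out_dir=str(tmp / "landscape"), label_lowest=2)
    result = run_pipeline(cfg)
    print("stages run:", result.ran)
    print("artifacts:", sorted(p.name for p in result.directory.iterdir()))

    again = run_pipeline(cfg)
    print("second run, stages skipped:", again.skipped)
print("The artifact directory holds the DRID array, cluster model, state "
      "trajectory, min.data/ts.data, the rendered tree and the waitlnpdf "
      "distributions -- the complete landscape record for one simulation.")
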