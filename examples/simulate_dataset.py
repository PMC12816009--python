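"""Write a synthetic multi-scorer dataset to disk with a manifest.

Generates three recordings, each with five noisy human scorings and
three model hypnodensities, and writes them in the package's plain-text
formats (stage-per-line hypnograms, probability CSVs) plus a JSON
manifest — the on-disk layout every CLI command consumes.
"""

import tempfile
from pathlib import Path

from sleepeval import read_manifest, simulate_record, write_manifest
from sleepeval.studies import default_model_noise, default_scorer_noise
from sleepeval.synthgen import default_dynamics

records = []
for i in range(3):
    rec, _truth = simulate_record(
        f"rec{i:02d}",
        default_dynamics(n_epochs=240),
        default_scorer_noise(),
        default_model_noise(),
        n_scorers=5,
        n_models=3,
        seed=40 + i,
    )
    records.append(rec)

out_dir = Path(tempfile.mkdtemp(prefix="sleepeval_demo_"))
manifest = write_manifest(records, out_dir)
print(f"wrote {sum(1 for _ in out_dir.iterdir())} files to {out_dir}")

back = read_manifest(manifest)
print(f"manifest lists {len(back)} recordings; first has "
      f"{len(back[0].scorer_hypnograms)} scorers and "
      f"{len(back[0].model_hypnodensities)} models of "
      f"{back[0].n_epochs} epochs each.")
print("the same manifest drives `sleepeval score/consensus/uncertainty/markers`.")
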