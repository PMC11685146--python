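"""Run the end-to-end pipeline and list the artifacts it writes.

generate -> extract -> select -> classify, from one validated config, with
every table written as diff-able CSV/text plus a log of the seeds, the
wavelet node-to-band assignment and any NaN-policy warnings.
"""

import tempfile
from pathlib import Path

from mifeatlab import RunConfig, run_pipeline

config = RunConfig(
    subjects=1,
    trials_per_subject=40,
    seed=7,
    effects=[{"class_id": 1, "channels": (8, 12), "band": (8.0, 13.0),
              "power_ratio": 4.0}],
    domains=("F", "P"),
    classifiers=("DT", "EL"),
    out_dir=str(Path(tempfile.mkdtemp()) / "run"),
)
out = run_pipeline(config)

print(f"artifacts in {out}:")
for f in sorted(out.iterdir()):
    print(f"  {f.name:26s} {f.stat().st_size:>8d} bytes")
print((out / "dimensions.txt").read_text().strip())
print("-> rerunning with the same config reproduces every file byte-for-byte.")
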