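"""The sign-consistency diagnostic on an external summary-statistics file.

Any per-variant G×E study that reports main and interaction estimates
with p-values can be screened without raw data.  Here a small TSV is
written, read back, and diagnosed at a priori thresholds.
"""

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from gxesign import read_summary_stats, sign_consistency_rate, write_report

rng = np.random.default_rng(4)
n = 40
beta = rng.normal(0, 1, n)
gamma = -np.sign(beta) * np.abs(rng.normal(0, 0.5, n))   # opposed pattern
stats = pd.DataFrame({
    "id": [f"gene{i}" for i in range(n)],
    "beta_main": beta,
    "p_main": rng.uniform(0, 0.04, n),
    "gamma_int": gamma,
    "p_int": rng.uniform(0, 0.1, n),
})

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "summary.tsv"
    stats.to_csv(path, sep="\t", index=False)
    fits = read_summary_stats(path)
    report = sign_consistency_rate(fits, p_int_threshold=0.05,
                                   p_main_threshold=0.05)
    write_report(report, Path(tmp) / "report.json", Path(tmp) / "report.md")
    print((Path(tmp) / "report.md").read_text())

print("A rate this close to 1 with an opposed majority is the signature of")
print("outcome scaling or threshold-based treatment endogeneity; a mixed")
print("pattern would have ruled both out as the sole driver.")
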