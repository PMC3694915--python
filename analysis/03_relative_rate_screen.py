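"""Tajima relative-rate screen on a synthetic alignment with one fast lineage.

Simulates a 10 kb clocklike triplet alignment plus a variant in which one
lineage's generation time is halved (doubling its per-year rate), and runs
the 1-df relative rate test, mirroring how a rate-deviant lineage (the
original analysis excluded *Aotus* on this basis) is detected and dropped
before clock dating.

Finding: the clocklike alignment passes (p >> 0.05); the accelerated
lineage is flagged at p < 1e-10.
"""

from pathlib import Path

import pandas as pd

from platydate.simulate import build_truth, simulate_alignment
from platydate.tajima import relative_rate_screen

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

NEWICK = "((A:10.0,B:10.0)AB:10.0,C:20.0)R;"
SEED = 7

rows = []
for label, gentimes in [("clocklike", {}), ("A_rate_doubled", {"A": 8.0})]:
    truth = build_truth(NEWICK, generation_times=gentimes, default_generation_time=16.0)
    aln = simulate_alignment(truth, length=10_000, seed=SEED)
    flagged, results = relative_rate_screen(aln, "C")
    for r in results:
        rows.append(
            {
                "scenario": label,
                "pair": f"{r.taxon_a}/{r.taxon_b}",
                "mA": r.mA,
                "mB": r.mB,
                "n_sites": r.n_sites_used,
                "chi2": round(r.chi2, 3),
                "p": f"{r.p:.3g}",
                "flagged": ", ".join(flagged) or "(none)",
            }
        )

report = pd.DataFrame(rows)
report.to_csv(OUT / "relative_rate_screen.tsv", sep="\t", index=False)
print(report.to_string(index=False))
print(f"wrote {OUT/'relative_rate_screen.tsv'}")
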