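"""Homopolymer-tract scan and null probabilities.

Scans a small bundled set of synthetic demo sequences for homopolymeric
tracts (length >= 5) and prints the uniform-composition null probability
for the tract lengths of interest (a 40-residue glutamine tract and a
58-residue serine tract).
"""

import pandas as pd

from common import results_dir, say

from polyqlab import pipeline as pl

# synthetic demo sequences (not database entries)
DEMO = [
    ("demo_polyQ40", "MAT" + "Q" * 40 + "PLAST"),
    ("demo_polyS58", "MG" + "S" * 58 + "KL"),
    ("demo_mixed", "MAQAQAQAQPPPPPPAKLLLLLG"),
    ("demo_none", "MARNDCEQGHILKMFPSTWYV"),
]


def main() -> None:
    out = results_dir("tracts")
    hits = pl.scan_homopolymer_tracts(DEMO, min_length=5)
    df = pd.DataFrame(hits, columns=["id", "residue", "start", "length"])
    df["null_probability"] = df.length.map(pl.tract_null_probability)
    df.to_csv(out / "tract_scan.csv", index=False)
    say(df.to_string(index=False))
    for L in (5, 40, 58):
        say(f"null probability of a {L}-tract: "
            f"{pl.tract_null_probability(L):.1e}")


if __name__ == "__main__":
    main()
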