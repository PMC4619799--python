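"""Compute the per-conformer descriptor tables for every generated set.

Reads the ensembles from step 01 and writes one CSV per chain length with
R_g, shape parameter w, secondary-structure percentages, mean coordination
number, contact order and the Maxwell volatility flag.
"""

import pandas as pd

from common import results_dir, say

from polyqlab import descriptors as desc
from polyqlab.structure import read_pdb

LENGTHS = (16, 24, 32)


def main() -> None:
    ens_dir = results_dir("ensembles")
    out = results_dir("descriptors")
    for n in LENGTHS:
        ens = read_pdb(ens_dir / f"set_n{n}.pdb")
        rows = []
        for c in ens:
            d = desc.compute_descriptors(c)
            rows.append({
                "id": c.id, "N": d.n_residues, "R_g": round(d.R_g, 3),
                "w": round(d.w, 4), "ss_alpha": d.ss_alpha,
                "ss_beta": d.ss_beta, "ss_turn": d.ss_turn,
                "ss_total": d.ss_total, "z_mean": round(d.z_mean, 4),
                "CO": None if d.CO is None else round(d.CO, 4),
                "n_contacts": d.n_contacts, "contact_mode": d.contact_mode,
                "volatile": d.volatile,
            })
        df = pd.DataFrame(rows)
        path = out / f"descriptors_n{n}.csv"
        df.to_csv(path, index=False)
        say(f"n={n}: stiff limit {desc.stiff_limit(n):.3f}, "
            f"{int(df.volatile.sum())}/{len(df)} volatile, "
            f"mean R_g {df.R_g.mean():.2f} A -> {path.name}")


if __name__ == "__main__":
    main()
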